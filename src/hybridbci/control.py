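"""Hierarchical 6×6 menu controller driven by decoded EEG events.

A command is issued through a fixed five-step protocol: gaze-select one
of six main categories (SSVEP), confirm with a single blink, gaze-select
one of six options, confirm with a single blink.  A double blink in
either confirmation phase undoes the pending selection and returns to
the previous menu.  Unexpected events (blinks while selecting, SSVEP
during a confirmation popup) are ignored and logged.

The 6×6 leaf grid plus the two blink calibration events gives the
38-command inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, List, Optional, Sequence, Tuple

from .preprocess import Epoch, RawStream, extract_epoch, make_bipolar
from .sim import BLINK_DOUBLE, BLINK_SINGLE, SSVEP_FREQS, ssvep_label

__all__ = ["Phase", "MenuSpec", "MenuState", "SessionLog", "step",
           "run_closed_loop", "command_inventory",
           "EVENT_SINGLE_BLINK", "EVENT_DOUBLE_BLINK", "ssvep_event"]


class Phase(Enum):
    MAIN_SELECT = "MAIN_SELECT"
    MAIN_CONFIRM = "MAIN_CONFIRM"
    SUB_SELECT = "SUB_SELECT"
    SUB_CONFIRM = "SUB_CONFIRM"
    DONE = "DONE"


EVENT_SINGLE_BLINK = "single_blink"
EVENT_DOUBLE_BLINK = "double_blink"


def ssvep_event(k: int) -> str:
    """Event name for a decoded gaze at stimulus index ``k`` (0–5)."""
    if not 0 <= k <= 5:
        raise ValueError(f"stimulus index must be 0..5, got {k}")
    return f"ssvep_{k}"


def all_events() -> List[str]:
    return [ssvep_event(k) for k in range(6)] + [EVENT_SINGLE_BLINK,
                                                 EVENT_DOUBLE_BLINK]


_DEFAULT_MAIN = ("daily life control", "calling", "food ordering",
                 "conversation control", "wheelchair control", "entertainment")


@dataclass(frozen=True)
class MenuSpec:
    """Labels of the 6 main categories and their 6 options each.

    ``stimulus_freqs`` maps on-screen position index (0–5) to flicker
    frequency; the same six flickers tag both menu levels.
    """

    main: Tuple[str, ...] = _DEFAULT_MAIN
    subs: Tuple[Tuple[str, ...], ...] = tuple(
        tuple(f"{cat} option {i + 1}" for i in range(6))
        for cat in _DEFAULT_MAIN
    )
    stimulus_freqs: Tuple[float, ...] = SSVEP_FREQS

    def __post_init__(self) -> None:
        n = len(self.main)
        if len(self.subs) != n:
            raise ValueError(f"{n} categories but {len(self.subs)} option rows")
        if any(len(row) != n for row in self.subs):
            raise ValueError("every category must have as many options as "
                             "there are categories")
        if len(set(self.stimulus_freqs)) != len(self.stimulus_freqs):
            raise ValueError("stimulus frequencies must be distinct")
        if len(self.stimulus_freqs) < n:
            raise ValueError("need one stimulus frequency per menu position")

    @property
    def n(self) -> int:
        return len(self.main)

    def event_for_frequency(self, freq: float) -> str:
        return ssvep_event(self.stimulus_freqs.index(freq))


@dataclass(frozen=True)
class MenuState:
    phase: Phase = Phase.MAIN_SELECT
    pending_main: Optional[int] = None
    pending_sub: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.pending_main is None) != (self.phase is Phase.MAIN_SELECT):
            raise ValueError(f"pending_main inconsistent with phase {self.phase}")
        sub_set = self.phase in (Phase.SUB_CONFIRM, Phase.DONE)
        if (self.pending_sub is not None) != sub_set:
            raise ValueError(f"pending_sub inconsistent with phase {self.phase}")


def step(state: MenuState, event: str) -> Tuple[MenuState, str]:
    """One transition of the menu state machine.

    Total over every (phase, event) pair: selection phases react to SSVEP
    events, confirmation phases to blinks, and everything else is a
    logged no-op.  Returns the new state and an action string
    ("prompt", "enter submenu", "undo", "issue (m, s)", or "no-op").
    """
    if event not in all_events():
        raise ValueError(f"unknown event {event!r}; valid: {all_events()}")
    is_ssvep = event.startswith("ssvep_")
    k = int(event.split("_")[1]) if is_ssvep else None

    if state.phase is Phase.MAIN_SELECT and is_ssvep:
        return MenuState(Phase.MAIN_CONFIRM, pending_main=k), "prompt"
    if state.phase is Phase.MAIN_CONFIRM:
        if event == EVENT_SINGLE_BLINK:
            return replace(state, phase=Phase.SUB_SELECT), "enter submenu"
        if event == EVENT_DOUBLE_BLINK:
            return MenuState(Phase.MAIN_SELECT), "undo"
    if state.phase is Phase.SUB_SELECT and is_ssvep:
        return MenuState(Phase.SUB_CONFIRM, pending_main=state.pending_main,
                         pending_sub=k), "prompt"
    if state.phase is Phase.SUB_CONFIRM:
        if event == EVENT_SINGLE_BLINK:
            done = MenuState(Phase.DONE, pending_main=state.pending_main,
                             pending_sub=state.pending_sub)
            return done, f"issue ({state.pending_main}, {state.pending_sub})"
        if event == EVENT_DOUBLE_BLINK:
            return MenuState(Phase.SUB_SELECT,
                             pending_main=state.pending_main), "undo"
    return state, "no-op"


@dataclass
class SessionLog:
    """Event/command/latency record of one closed-loop run."""

    events: List[dict] = field(default_factory=list)
    issued_commands: List[Tuple[int, int]] = field(default_factory=list)

    def response_times(self) -> dict:
        """Per-event-class latencies in seconds (epoch boundary to action)."""
        out: dict = {}
        for ev in self.events:
            if ev["action"] == "no-op":
                continue
            out.setdefault(ev["event"], []).append(ev["latency"])
        return out

    def decoded_correct(self) -> dict:
        """Per-event-class (correct, total) counts when truth is known."""
        out: dict = {}
        for ev in self.events:
            truth = ev.get("true_label")
            if truth is None:
                continue
            c, t = out.get(truth, (0, 0))
            out[truth] = (c + (ev["decoded_label"] == truth), t + 1)
        return out


def _label_to_event(label: str, menu: MenuSpec) -> Optional[str]:
    if label == BLINK_SINGLE:
        return EVENT_SINGLE_BLINK
    if label == BLINK_DOUBLE:
        return EVENT_DOUBLE_BLINK
    for i, f in enumerate(menu.stimulus_freqs):
        if ssvep_label(f) == label:
            return ssvep_event(i)
    return None


def run_closed_loop(stream: RawStream, decoder: Callable[[Epoch], str],
                    menu: MenuSpec = MenuSpec(), epoch_s: float = 2.0,
                    truth_events: Optional[Sequence[dict]] = None,
                    stop_on_done: bool = False) -> SessionLog:
    """Drive the menu with consecutive decoded epochs of a stream.

    The stream is consumed in back-to-back non-overlapping ``epoch_s``
    windows (bipolar derivation applied first when O1/O2 are present);
    each decoded label becomes a state-machine event.  When a
    ground-truth event log (from :func:`hybridbci.sim.make_session_stream`)
    is supplied, each epoch is annotated with the true label active at
    its onset.  After a command is issued the machine resets to the main
    menu (or stops when ``stop_on_done``).
    """
    if stream.duration < epoch_s:
        raise ValueError(
            f"stream of {stream.duration} s is shorter than one "
            f"{epoch_s} s epoch"
        )
    if stream.samples.shape[0] > 1:
        stream = make_bipolar(stream)
    log = SessionLog()
    state = MenuState()
    n_epochs = int(stream.duration // epoch_s)
    for i in range(n_epochs):
        onset = stream.t0 + i * epoch_s
        epoch = extract_epoch(stream, onset, epoch_s)
        label = decoder(epoch)
        event = _label_to_event(label, menu)
        true_label = None
        if truth_events is not None:
            for ev in truth_events:
                if ev["onset"] <= onset < ev["onset"] + ev["duration"]:
                    true_label = ev["label"]
                    break
        if event is None:
            state2, action = state, "no-op"
        else:
            state2, action = step(state, event)
        log.events.append({
            "time": onset + epoch_s,  # action instant = epoch end
            "event": event,
            "decoded_label": label,
            "true_label": true_label,
            "action": action,
            "latency": epoch_s,
            "phase": state2.phase.value,
        })
        state = state2
        if state.phase is Phase.DONE:
            log.issued_commands.append((state.pending_main, state.pending_sub))
            if stop_on_done:
                break
            state = MenuState()
    return log


def command_inventory(menu: MenuSpec = MenuSpec()) -> dict:
    """Leaf-command and calibration-event counts (6×6 + 2 = 38 by default)."""
    leaves = menu.n * menu.n
    return {"leaf_commands": leaves, "blink_commands": 2,
            "total": leaves + 2}
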