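"""Experimental designs for masked and unmasked arrow-priming tasks.

A :class:`TaskDesign` captures the stimulus/timing schedule of one condition:
which SOAs are sampled, how they are grouped into blocks, how often each
SOA x congruency cell repeats, and the stimulus duration bookkeeping needed by
the models (prime duration, prime-to-mask interval, mask duration).

SOA is referenced to prime onset in the unmasked task and to mask onset in the
masked task.  All SOA grids use a 20 ms step.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOA_STEP_MS = 20

#: canonical column order of a trial table
TRIAL_COLUMNS = [
    "participant",
    "condition",
    "block_index",
    "trial_index",
    "soa_ms",
    "congruency",
    "prime_dir",
    "target_dir",
    "response",
    "rt_ms",
    "correct",
    "excluded",
]


@dataclass(frozen=True)
class TaskDesign:
    """Stimulus/timing schedule of one experimental condition.

    Parameters
    ----------
    name : str
        Preset label.
    task_kind : {"unmasked", "masked"}
    prime_duration : int
        Prime duration in ms (20 throughout).
    mask_duration : int or None
        Mask duration in ms; None for unmasked tasks.
    prime_mask_interval : int or None
        Prime offset to mask onset interval in ms; None for unmasked tasks.
    soa_blocks : tuple of tuple of int
        Ordered SOA sets (ms), one tuple per block.
    repeats_per_cell : int
        Repetitions of each SOA x congruency cell within its block.
    rt_limit : int
        Response time limit in ms.
    soa_reference : {"prime_onset", "mask_onset"}
        Onset from which SOA (and the temporal-expectation clock) is measured.
    """

    name: str
    task_kind: str
    prime_duration: int
    mask_duration: int | None
    prime_mask_interval: int | None
    soa_blocks: tuple[tuple[int, ...], ...]
    repeats_per_cell: int
    rt_limit: int
    soa_reference: str

    def __post_init__(self) -> None:
        if self.task_kind not in ("unmasked", "masked"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.repeats_per_cell < 1:
            raise ValueError("repeats_per_cell must be >= 1")
        expect_ref = "mask_onset" if self.task_kind == "masked" else "prime_onset"
        if self.soa_reference != expect_ref:
            raise ValueError(
                f"soa_reference must be {expect_ref!r} for a {self.task_kind} task"
            )
        for block in self.soa_blocks:
            for soa in block:
                if soa < 0 or soa % SOA_STEP_MS:
                    raise ValueError(
                        f"SOA {soa} is not a nonnegative multiple of {SOA_STEP_MS} ms"
                    )

    @property
    def all_soas(self) -> np.ndarray:
        """Sorted union of the SOA sets of all blocks (ms)."""
        return np.unique(np.concatenate([np.asarray(b) for b in self.soa_blocks]))

    @property
    def n_blocks(self) -> int:
        return len(self.soa_blocks)

    @property
    def reference_offset_ms(self) -> int:
        """Delay from prime onset to the SOA reference onset (ms).

        0 for unmasked tasks; prime duration + prime-to-mask interval for
        masked tasks (the mask onset).
        """
        if self.task_kind == "unmasked":
            return 0
        return self.prime_duration + self.prime_mask_interval

    @property
    def n_trials(self) -> int:
        return sum(len(b) for b in self.soa_blocks) * 2 * self.repeats_per_cell

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["soa_blocks"] = [list(b) for b in self.soa_blocks]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TaskDesign":
        d = json.loads(text)
        d["soa_blocks"] = tuple(tuple(int(s) for s in b) for b in d["soa_blocks"])
        return cls(**d)


def _grid(lo: int, hi: int) -> tuple[int, ...]:
    return tuple(range(lo, hi + 1, SOA_STEP_MS))


def _blocked(soas: tuple[int, ...], n_blocks: int) -> tuple[tuple[int, ...], ...]:
    size = len(soas) // n_blocks
    return tuple(soas[i * size : (i + 1) * size] for i in range(n_blocks))


def _masked(name, blocks, repeats, rt_limit, interval=60):
    return TaskDesign(
        name=name,
        task_kind="masked",
        prime_duration=20,
        mask_duration=100,
        prime_mask_interval=interval,
        soa_blocks=blocks,
        repeats_per_cell=repeats,
        rt_limit=rt_limit,
        soa_reference="mask_onset",
    )


_PRESETS: dict[str, TaskDesign] = {
    # 50 SOAs 0-980 ms, 16 repeats per cell, RT limit 1500 ms
    "huang_unmasked": TaskDesign(
        name="huang_unmasked",
        task_kind="unmasked",
        prime_duration=20,
        mask_duration=None,
        prime_mask_interval=None,
        soa_blocks=(_grid(0, 980),),
        repeats_per_cell=16,
        rt_limit=1500,
        soa_reference="prime_onset",
    ),
    "huang_masked": _masked("huang_masked", (_grid(0, 980),), 16, 1500),
    # temporal-context conditions: 40 SOAs 0-780 ms split into 1/2/4/10 blocks
    "tc_40soa": _masked("tc_40soa", _blocked(_grid(0, 780), 1), 12, 1500),
    "tc_20soa": _masked("tc_20soa", _blocked(_grid(0, 780), 2), 12, 1500),
    "tc_10soa": _masked("tc_10soa", _blocked(_grid(0, 780), 4), 12, 1500),
    "tc_4soa": _masked("tc_4soa", _blocked(_grid(0, 780), 10), 12, 1500),
    # prime-to-mask interval manipulation: 32 SOAs 0-620 ms, 20 repeats
    "int0": _masked("int0", (_grid(0, 620),), 20, 1000, interval=0),
    "int60": _masked("int60", (_grid(0, 620),), 20, 1000, interval=60),
}

PRESET_NAMES = tuple(_PRESETS)


def make_design(preset_name: str) -> TaskDesign:
    """Return one of the built-in experimental designs.

    Raises
    ------
    KeyError
        If ``preset_name`` is unknown; the message lists valid presets.
    """
    try:
        return _PRESETS[preset_name]
    except KeyError:
        raise KeyError(
            f"unknown design preset {preset_name!r}; valid presets: "
            + ", ".join(PRESET_NAMES)
        ) from None


def generate_trial_sequence(
    design: TaskDesign,
    seed: int,
    block_order_random: bool = True,
    participant: str = "p01",
) -> pd.DataFrame:
    """Generate a randomized trial sequence for one participant.

    Within each block every SOA x congruency cell appears exactly
    ``repeats_per_cell`` times in uniformly shuffled order.  Prime direction is
    sampled uniformly per trial; target direction is set by congruency.  Block
    order is shuffled iff ``block_order_random`` (the block-order draw is
    consumed first so that trial shuffles are reproducible either way).

    Returns a trial table (one row per trial, session order) with RT fields
    unset.
    """
    rng = np.random.default_rng(seed)
    order = np.arange(design.n_blocks)
    perm = rng.permutation(design.n_blocks)  # consumed even if unused
    if block_order_random:
        order = perm

    rows = []
    trial_index = 0
    for block_index in order:
        soas = design.soa_blocks[block_index]
        cells = [
            (soa, cong)
            for soa in soas
            for cong in ("C", "IC")
            for _ in range(design.repeats_per_cell)
        ]
        idx = rng.permutation(len(cells))
        for i in idx:
            soa, cong = cells[i]
            prime_dir = "L" if rng.random() < 0.5 else "R"
            if cong == "C":
                target_dir = prime_dir
            else:
                target_dir = "R" if prime_dir == "L" else "L"
            rows.append(
                (
                    participant,
                    design.name,
                    int(block_index),
                    trial_index,
                    int(soa),
                    cong,
                    prime_dir,
                    target_dir,
                    None,
                    np.nan,
                    None,
                    False,
                )
            )
            trial_index += 1

    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
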