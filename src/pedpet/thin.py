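"""Virtual dose reduction by random deletion of list-mode prompt events.

Deleting each prompt independently with probability 1-S leaves a stream
whose counting statistics match an acquisition at a fraction S of the
injected activity, provided the count rate sits in the linear (sub-NEC-peak)
regime where randoms and dead time are negligible — the regime the
simulator operates in by construction.  Deleting at threshold S therefore
emulates a virtual reduction of the injected dose by a factor 1/S.

The deviate driving each deletion comes from RANECU, L'Ecuyer's combined
multiplicative linear congruential generator, one deviate per prompt; time
and tag records always survive thinning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .listmode import KIND_PROMPT, ListModeData

__all__ = [
    "RANECU_M1", "RANECU_M2", "DEFAULT_LEVELS",
    "ThinningSpec", "ranecu_next", "ranecu_sequence",
    "thin_listmode", "make_level_set",
]

RANECU_M1 = 2147483563
RANECU_M2 = 2147483399
_A1 = 40014
_A2 = 40692
_SCALE = 4.656613e-10

#: Standard reduced count levels (fractions of the original prompts).
DEFAULT_LEVELS = (0.75, 0.50, 0.35, 0.20, 0.10)


def _check_state(state: tuple[int, int]) -> tuple[int, int]:
    s1, s2 = int(state[0]), int(state[1])
    if not (0 < s1 < RANECU_M1):
        raise ValueError(f"seed component 1 must be in (0, {RANECU_M1}), got {s1}")
    if not (0 < s2 < RANECU_M2):
        raise ValueError(f"seed component 2 must be in (0, {RANECU_M2}), got {s2}")
    return s1, s2


@dataclass(frozen=True)
class ThinningSpec:
    """Retention fraction S and the RANECU seed pair driving the deletions."""

    retention: float
    seed_pair: tuple[int, int] = (12345, 67890)

    def __post_init__(self) -> None:
        if not (0.0 < self.retention <= 1.0):
            raise ValueError(f"retention must be in (0, 1], got {self.retention}")
        _check_state(self.seed_pair)


def ranecu_next(state: tuple[int, int]) -> tuple[float, tuple[int, int]]:
    """One RANECU deviate: returns (u in (0,1), new state).

    The combined generator advances two multiplicative LCGs
    (40014 mod 2147483563 and 40692 mod 2147483399), takes their difference
    modulo 2147483562 (mapped into [1, 2147483562]) and scales by
    4.656613e-10.
    """
    s1, s2 = _check_state(state)
    s1 = (_A1 * s1) % RANECU_M1
    s2 = (_A2 * s2) % RANECU_M2
    z = s1 - s2
    if z < 1:
        z += RANECU_M1 - 1
    return z * _SCALE, (s1, s2)


@njit(cache=True)
def _ranecu_bulk(s1, s2, out):  # pragma: no cover
    for i in range(out.shape[0]):
        s1 = (40014 * s1) % 2147483563
        s2 = (40692 * s2) % 2147483399
        z = s1 - s2
        if z < 1:
            z += 2147483562
        out[i] = z * 4.656613e-10
    return s1, s2


def ranecu_sequence(state: tuple[int, int], n: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Vectorised stream of ``n`` RANECU deviates (same sequence as ranecu_next)."""
    s1, s2 = _check_state(state)
    out = np.empty(int(n), dtype=np.float64)
    s1, s2 = _ranecu_bulk(np.int64(s1), np.int64(s2), out)
    return out, (int(s1), int(s2))


def thin_listmode(data: ListModeData, spec: ThinningSpec) -> ListModeData:
    """Randomly delete prompts at retention threshold S.

    One deviate is drawn per prompt, in stream order; the prompt is deleted
    iff its deviate is strictly larger than S.  Time and tag records are
    copied unconditionally, so the retained prompts are an order-preserving
    subsequence of the input interleaved with the original housekeeping
    records.  The header count level is multiplied by S.
    """
    S = spec.retention
    records = data.records
    is_prompt = records["kind"] == KIND_PROMPT
    n_prompts = int(is_prompt.sum())
    u, _ = ranecu_sequence(spec.seed_pair, n_prompts)
    keep = np.ones(records.shape[0], dtype=bool)
    keep[is_prompt] = u <= S
    return ListModeData(
        geometry=data.geometry,
        records=records[keep].copy(),
        acquisition_duration=data.acquisition_duration,
        count_level=data.count_level * S,
        count_scale=data.count_scale,
        image_grid=data.image_grid,
        source_meta=data.source_meta,
    )


def _level_seed(base_seed: int, index: int) -> tuple[int, int]:
    """Deterministic per-level RANECU seed pair derived from a base seed.

    The level index is mixed into both components with distinct odd
    multipliers so different levels get decorrelated streams.
    """
    if base_seed < 0:
        raise ValueError("base_seed must be non-negative")
    s1 = (base_seed * 2654435761 + 7919 * (index + 1) + 1) % (RANECU_M1 - 1) + 1
    s2 = (base_seed * 1597334677 + 104729 * (index + 1) + 1) % (RANECU_M2 - 1) + 1
    return int(s1), int(s2)


def make_level_set(
    data: ListModeData,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    base_seed: int = 0,
) -> dict[float, ListModeData]:
    """Thin the ORIGINAL stream once per level (not nested).

    Returns a mapping level -> dataset including the untouched original
    under level 1.0, i.e. six count levels for the default five reductions.
    """
    levels = tuple(levels)
    if len(set(levels)) != len(levels):
        raise ValueError("duplicate levels")
    for lv in levels:
        if not (0.0 < lv < 1.0):
            raise ValueError(f"levels must lie in (0, 1), got {lv}")
    out: dict[float, ListModeData] = {1.0: data}
    for i, lv in enumerate(levels):
        spec = ThinningSpec(retention=lv, seed_pair=_level_seed(base_seed, i))
        out[lv] = thin_listmode(data, spec)
    return out
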