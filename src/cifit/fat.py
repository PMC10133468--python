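"""Frequency allocation tables (FATs): the standard map and the tonotopic map.

A FAT partitions the processor's analysis range into contiguous bands, one per
electrode channel.  Two tables are modelled:

* the fixed *standard* FAT: 16 enabled channels tiling 238-8,598 Hz
  (log-spaced by default, overridable by an explicit table of lower bounds);
* the per-subject *tonotopic* (imaging-based) FAT, where each channel's lower
  bound is set to its contact's Greenwood place frequency, a virtual
  (phantom) channel below the most apical contact carries the low-frequency
  content from 238 Hz up, basal channels whose place frequency exceeds the
  processor ceiling are disabled, and a minimum-low-frequency rule set is
  enforced by a deterministic repair step.

The rule set requires at least 2 enabled channels (virtual channel included)
stimulated below 1,000 Hz, 4 below 2,000 Hz, 7 below 4,000 Hz, and the most
basal enabled channel at or below 8,598 Hz.  Strict tonotopic alignment can
violate these minima for shallow insertions; the repair lowers the offending
bounds onto a geometric grid between the last compliant bound and the unmet
threshold, leaving all other channels untouched.

Frequency-to-place mismatch is quantified per channel as
``log2(place_frequency / assigned_frequency)`` in octaves, where the assigned
frequency defaults to the geometric mean of the channel's band edges
(configurable to the lower bound, under which a freshly built tonotopic FAT
has zero mismatch by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GLOBAL_MIN_HZ",
    "GLOBAL_MAX_HZ",
    "Channel",
    "FrequencyAllocationTable",
    "RuleSet",
    "Violation",
    "MismatchProfile",
    "standard_fat",
    "build_tonotopic_fat",
    "validate_fat",
    "mismatch_profile",
]

GLOBAL_MIN_HZ = 238.0
GLOBAL_MAX_HZ = 8598.0

VIRTUAL_CHANNEL_INDEX = 0


@dataclass(frozen=True)
class Channel:
    """One FAT band. Index 0 is the virtual (phantom) channel."""

    channel_index: int
    lower_bound: float  # Hz
    upper_bound: float  # Hz
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.lower_bound <= 0 or self.upper_bound <= 0:
            raise ValueError(f"channel {self.channel_index}: bounds must be positive")
        if self.enabled and not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"channel {self.channel_index}: lower bound {self.lower_bound} "
                f">= upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class FrequencyAllocationTable:
    channels: tuple[Channel, ...]
    global_min: float = GLOBAL_MIN_HZ
    global_max: float = GLOBAL_MAX_HZ
    has_virtual_channel: bool = False
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        idx = [c.channel_index for c in self.channels]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique and ascending")
        if self.has_virtual_channel != (idx[:1] == [VIRTUAL_CHANNEL_INDEX]):
            raise ValueError("has_virtual_channel inconsistent with channel indices")

    @property
    def enabled_channels(self) -> tuple[Channel, ...]:
        return tuple(c for c in self.channels if c.enabled)

    def channel(self, index: int) -> Channel:
        for c in self.channels:
            if c.channel_index == index:
                return c
        raise KeyError(f"no channel with index {index}")

    def lower_bounds(self, enabled_only: bool = True) -> np.ndarray:
        chans = self.enabled_channels if enabled_only else self.channels
        return np.array([c.lower_bound for c in chans])


@dataclass(frozen=True)
class RuleSet:
    """Minimum-count rules for low-frequency coverage plus the basal ceiling.

    ``min_channels_below`` lists (threshold Hz, minimum enabled-channel count)
    pairs; a channel "stimulated below" a threshold is an enabled channel whose
    lower bound is below it.  The virtual channel counts.
    """

    min_channels_below: tuple[tuple[float, int], ...] = (
        (1000.0, 2),
        (2000.0, 4),
        (4000.0, 7),
    )
    basal_max: float = GLOBAL_MAX_HZ

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "min_channels_below", tuple(tuple(p) for p in self.min_channels_below)
        )
        thr = [t for t, _ in self.min_channels_below]
        cnt = [c for _, c in self.min_channels_below]
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if any(b < a for a, b in zip(cnt, cnt[1:])):
            raise ValueError("counts must be non-decreasing")


@dataclass(frozen=True)
class Violation:
    rule: str
    detail: str
    threshold: float | None = None
    required: int | None = None
    observed: float | None = None


@dataclass(frozen=True)
class MismatchProfile:
    """Signed octave offsets log2(place / assigned) for enabled physical channels."""

    contact_indices: np.ndarray
    per_contact_octaves: np.ndarray
    median: float
    iqr: float

    @property
    def median_absolute(self) -> float:
        return float(np.median(np.abs(self.per_contact_octaves)))


def _tile_upper_bounds(
    ordered: list[tuple[int, float, bool]], global_max: float
) -> list[Channel]:
    """Assign upper bounds so enabled bands tile contiguously.

    ``ordered`` holds (index, lower_bound, enabled) apical->basal.  Each
    enabled channel's upper bound is the next enabled channel's lower bound;
    the top enabled channel is capped at ``global_max`` (or the first disabled
    bound above it, whichever is lower).  Disabled channels keep degenerate
    bookkeeping bounds equal to their (out-of-range) place bound.
    """
    channels: list[Channel] = []
    enabled_positions = [i for i, (_, _, en) in enumerate(ordered) if en]
    for pos, (idx, lo, en) in enumerate(ordered):
        if not en:
            channels.append(Channel(idx, lo, lo * (1 + 1e-9), enabled=False))
            continue
        nxt = next((p for p in enabled_positions if p > pos), None)
        if nxt is not None:
            hi = ordered[nxt][1]
        else:
            above = [b for (_, b, e) in ordered[pos + 1:] if not e]
            hi = min([global_max] + above)
        channels.append(Channel(idx, lo, hi, enabled=True))
    return channels


def standard_fat(
    lower_bounds: Sequence[float] | None = None,
    n_channels: int = 16,
    global_min: float = GLOBAL_MIN_HZ,
    global_max: float = GLOBAL_MAX_HZ,
    rules: RuleSet | None = None,
) -> FrequencyAllocationTable:
    """The fixed control FAT: all channels enabled, no virtual channel.

    Without an explicit table, lower bounds are log-spaced over
    [global_min, global_max): channel k gets
    ``global_min * (global_max/global_min)**((k-1)/n)``.  Clinical default
    tables are device-specific and can be supplied as ``lower_bounds``.
    """
    if lower_bounds is None:
        k = np.arange(n_channels)
        lows = global_min * (global_max / global_min) ** (k / n_channels)
    else:
        lows = np.asarray(lower_bounds, dtype=float)
        n_channels = len(lows)
        if np.any(np.diff(lows) <= 0):
            raise ValueError(
                "standard FAT table invalid: lower bounds must strictly increase"
            )
    ordered = [(i + 1, float(lo), True) for i, lo in enumerate(lows)]
    fat = FrequencyAllocationTable(
        _tile_upper_bounds(ordered, global_max),
        global_min=global_min,
        global_max=global_max,
        has_virtual_channel=False,
    )
    violations = validate_fat(fat, rules or RuleSet())
    if violations:
        raise ValueError(f"standard FAT table invalid: {violations}")
    return fat


def _repair_rules(bounds: list[float], rules: RuleSet, global_min: float) -> list[float]:
    """Lower offending bounds so every minimum-count rule is met.

    ``bounds`` are the enabled channels' lower bounds apical->basal.  For each
    unmet threshold, the first ``required`` channels must lie below it; the
    ones at or above are moved onto a geometric grid strictly between the
    previous compliant bound and the threshold.  Deterministic; channels
    beyond ``required`` are never touched.
    """
    out = list(bounds)
    for threshold, required in rules.min_channels_below:
        have = sum(1 for b in out if b < threshold)
        if have >= required:
            continue
        prev = out[have - 1] if have > 0 else global_min
        n_new = required - have
        for j in range(n_new):
            out[have + j] = prev * (threshold / prev) ** ((j + 1) / (n_new + 1))
    return out


def build_tonotopic_fat(
    place_freqs: Sequence[float],
    rules: RuleSet | None = None,
    global_min: float = GLOBAL_MIN_HZ,
    global_max: float = GLOBAL_MAX_HZ,
    subject_id: str = "",
) -> FrequencyAllocationTable:
    """Build the imaging-based FAT from per-contact place frequencies.

    ``place_freqs`` are ordered apical->basal and strictly increasing.  Steps:

    1. virtual channel (index 0) enabled from ``global_min`` (238 Hz) up to
       the most apical contact's place frequency;
    2. each physical channel's lower bound set to its contact's place
       frequency (floored at the virtual channel's upper bound when the
       contact sits below the processor floor);
    3. channels whose lower bound would reach ``global_max`` disabled;
    4. the rule set enforced by the deterministic repair;
    5. contiguous upper bounds assigned.

    Raises if fewer channels remain than the largest rule count + 1 requires.
    """
    rules = rules or RuleSet()
    place = np.asarray(place_freqs, dtype=float)
    if np.any(np.diff(place) <= 0):
        raise ValueError("place frequencies must strictly increase apical->basal")

    # contacts whose place frequency falls below the processor floor cannot
    # keep tonotopic bounds: spread them geometrically between the floor and
    # the first in-range place frequency (the virtual channel keeps 238 Hz)
    n_sub = int(np.sum(place <= global_min))
    if n_sub:
        nxt = float(place[n_sub]) if n_sub < len(place) else global_max
        sub = [
            global_min * (nxt / global_min) ** ((j + 1) / (n_sub + 1))
            for j in range(n_sub)
        ]
        physical = sub + [float(f) for f in place[n_sub:]]
    else:
        physical = [float(f) for f in place]
    lows = [("virtual", global_min)] + [
        (i + 1, f) for i, f in enumerate(physical)
    ]
    enabled = [lo < global_max for _, lo in lows]
    n_usable = sum(enabled)
    max_required = max(c for _, c in rules.min_channels_below)
    if n_usable < max_required + 1:
        raise ValueError(
            f"only {n_usable} usable channels; rule set needs at least "
            f"{max_required + 1} (largest minimum count + basal channel)"
        )

    enabled_bounds = [lo for (_, lo), en in zip(lows, enabled) if en]
    repaired = _repair_rules(enabled_bounds, rules, global_min)
    it = iter(repaired)
    ordered = [
        (0 if idx == "virtual" else idx, next(it) if en else lo, en)
        for (idx, lo), en in zip(lows, enabled)
    ]
    return FrequencyAllocationTable(
        _tile_upper_bounds(ordered, global_max),
        global_min=global_min,
        global_max=global_max,
        has_virtual_channel=True,
        subject_id=subject_id,
    )


def validate_fat(
    fat: FrequencyAllocationTable, rules: RuleSet | None = None
) -> list[Violation]:
    """Check structural invariants and the rule set; empty list iff compliant."""
    rules = rules or RuleSet()
    out: list[Violation] = []
    enabled = fat.enabled_channels
    if not enabled:
        return [Violation("structure", "no enabled channels")]

    for a, b in zip(enabled, enabled[1:]):
        if not np.isclose(a.upper_bound, b.lower_bound, rtol=1e-9):
            out.append(
                Violation(
                    "contiguity",
                    f"channel {a.channel_index} upper {a.upper_bound:.6g} Hz != "
                    f"channel {b.channel_index} lower {b.lower_bound:.6g} Hz",
                )
            )
    if not np.isclose(enabled[0].lower_bound, fat.global_min, rtol=1e-9):
        out.append(
            Violation(
                "global_min",
                f"lowest enabled lower bound {enabled[0].lower_bound:.6g} Hz "
                f"!= {fat.global_min:g} Hz",
                observed=enabled[0].lower_bound,
            )
        )
    if enabled[-1].upper_bound > fat.global_max * (1 + 1e-9):
        out.append(
            Violation(
                "global_max",
                f"top enabled upper bound {enabled[-1].upper_bound:.6g} Hz "
                f"exceeds {fat.global_max:g} Hz",
                observed=enabled[-1].upper_bound,
            )
        )

    lows = fat.lower_bounds(enabled_only=True)
    for threshold, required in rules.min_channels_below:
        observed = int(np.sum(lows < threshold))
        if observed < required:
            out.append(
                Violation(
                    "min_channels_below",
                    f"{observed} enabled channels below {threshold:g} Hz, "
                    f"need {required}",
                    threshold=threshold,
                    required=required,
                    observed=observed,
                )
            )
    basal_low = enabled[-1].lower_bound
    if basal_low > rules.basal_max:
        out.append(
            Violation(
                "basal_max",
                f"most basal enabled lower bound {basal_low:.6g} Hz exceeds "
                f"{rules.basal_max:g} Hz",
                threshold=rules.basal_max,
                observed=basal_low,
            )
        )
    return out


def assigned_frequencies(
    fat: FrequencyAllocationTable, representative: str = "geometric_mean"
) -> dict[int, float]:
    """Representative assigned frequency per enabled physical channel."""
    if representative not in ("geometric_mean", "lower_bound"):
        raise ValueError(f"unknown representative {representative!r}")
    out = {}
    for c in fat.enabled_channels:
        if c.channel_index == VIRTUAL_CHANNEL_INDEX:
            continue
        if representative == "geometric_mean":
            out[c.channel_index] = float(np.sqrt(c.lower_bound * c.upper_bound))
        else:
            out[c.channel_index] = float(c.lower_bound)
    return out


def mismatch_profile(
    fat: FrequencyAllocationTable,
    place_freqs: Sequence[float],
    representative: str = "geometric_mean",
) -> MismatchProfile:
    """Frequency-to-place mismatch, in signed octaves, per enabled channel.

    ``place_freqs[i]`` is the place frequency of contact ``i + 1`` (apical
    numbering), matching physical channel ``i + 1``.  The virtual channel has
    no contact and is excluded.  Positive offsets mean the channel is assigned
    a frequency below its tonotopic place.
    """
    place = np.asarray(place_freqs, dtype=float)
    assigned = assigned_frequencies(fat, representative)
    n_physical = sum(1 for c in fat.channels if c.channel_index != VIRTUAL_CHANNEL_INDEX)
    if n_physical != len(place):
        raise ValueError(
            f"FAT has {n_physical} physical channels but {len(place)} "
            "place frequencies given"
        )
    idx = np.array(sorted(assigned))
    offsets = np.array([np.log2(place[i - 1] / assigned[i]) for i in idx])
    q1, q3 = np.percentile(offsets, [25, 75])
    return MismatchProfile(
        contact_indices=idx,
        per_contact_octaves=offsets,
        median=float(np.median(offsets)),
        iqr=float(q3 - q1),
    )


def cohort_mismatch_summary(profiles: Sequence[MismatchProfile]):
    """Per-contact and pooled median/IQR of octave mismatch across subjects.

    Returns (per_contact, pooled) where per_contact maps contact index ->
    (median, IQR, n_subjects) over the subjects in which that contact's
    channel is enabled, mirroring a per-electrode mismatch figure.
    """
    by_contact: dict[int, list[float]] = {}
    pooled: list[float] = []
    for p in profiles:
        for i, v in zip(p.contact_indices, p.per_contact_octaves):
            by_contact.setdefault(int(i), []).append(float(v))
        pooled.extend(p.per_contact_octaves.tolist())
    per_contact = {}
    for i, vals in sorted(by_contact.items()):
        q1, q3 = np.percentile(vals, [25, 75])
        per_contact[i] = (float(np.median(vals)), float(q3 - q1), len(vals))
    q1, q3 = np.percentile(pooled, [25, 75])
    return per_contact, (float(np.median(pooled)), float(q3 - q1), len(pooled))
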