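"""Physicochemical characterization of an ORF product.

Covers the features used to describe the spacer-encoded protein: the
Kyte–Doolittle hydropathy profile and overall index (rescaled from the
native [−4.5, +4.5] range onto [0, 1]), charged-residue censuses over
residue intervals, degenerate hydrophobic-motif search (``I[VL]LY[CR]``
and friends), amphipathic segmentation of the profile, and predicted
average molecular mass for gel-band comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight

from .seqcore import Interval, ProtSeq

#: Kyte & Doolittle hydropathy values, spanning Arg (−4.5) to Ile (+4.5).
KD_SCALE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

KD_MIN, KD_MAX = -4.5, 4.5

POSITIVE_RESIDUES = frozenset("RK")
POSITIVE_RESIDUES_WITH_H = frozenset("RKH")
NEGATIVE_RESIDUES = frozenset("DE")

#: Hydrophobic pentapeptide motif and its observed variants.
DEFAULT_MOTIF = "I[VL]LY[CR]"


@dataclass
class HydropathyProfile:
    """Sliding-window Kyte–Doolittle means plus the overall scaled index."""

    window: int
    per_residue_raw: np.ndarray
    scaled_index: float

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not 0.0 <= self.scaled_index <= 1.0:
            raise ValueError("scaled index outside [0, 1]")

    @property
    def scaled(self) -> np.ndarray:
        """Per-window means rescaled onto [0, 1]."""
        return (self.per_residue_raw - KD_MIN) / (KD_MAX - KD_MIN)


@dataclass
class ChargeCensus:
    """Counts of charged residues inside an interval and sequence-wide."""

    interval: tuple[int, int]  # 1-based inclusive
    n_positive: int
    n_negative: int
    total_positive: int
    total_negative: int
    positive_set: str
    negative_set: str


@dataclass
class MotifHit:
    pattern: str
    start_1based: int
    matched: str


def _kd_values(p: ProtSeq) -> np.ndarray:
    seq = p.residues
    if not seq:
        raise ValueError("cannot profile an empty protein")
    try:
        return np.array([KD_SCALE[a] for a in seq], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no hydropathy value for residue {exc}") from None


def kd_raw_mean(p: ProtSeq) -> float:
    """Mean per-residue Kyte–Doolittle value (a.k.a. GRAVY)."""
    return float(_kd_values(p).mean())


def kd_index(p: ProtSeq) -> float:
    """Overall hydropathic index rescaled linearly onto [0, 1].

    The linear map ``(mean + 4.5) / 9`` sends the most hydrophilic
    residue (Arg, −4.5) to 0 and the most hydrophobic (Ile, +4.5) to 1.
    """
    return (kd_raw_mean(p) - KD_MIN) / (KD_MAX - KD_MIN)


def kd_profile(p: ProtSeq, window: int = 9) -> HydropathyProfile:
    """Sliding-window hydropathy profile (valid windows only).

    The profile has ``len(p) − window + 1`` values; entry ``i`` is the
    mean over residues ``i .. i+window−1`` (0-based).
    """
    values = _kd_values(p)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > len(values):
        raise ValueError(
            f"window {window} exceeds protein length {len(values)}"
        )
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    return HydropathyProfile(
        window=window,
        per_residue_raw=means,
        scaled_index=(float(values.mean()) - KD_MIN) / (KD_MAX - KD_MIN),
    )


def charge_census(
    p: ProtSeq,
    interval: tuple[int, int],
    include_histidine: bool = False,
) -> ChargeCensus:
    """Count positive/negative residues in a 1-based inclusive interval.

    Positives are R/K (optionally +H); negatives are D/E. The census also
    reports whole-sequence totals so statements like "13 of the total 18
    positively charged residues fall in the core" can be made directly.
    """
    seq = p.residues
    lo, hi = interval
    if not (1 <= lo <= hi <= len(seq)):
        raise ValueError(
            f"interval {interval} invalid for protein of length {len(seq)}"
        )
    pos = POSITIVE_RESIDUES_WITH_H if include_histidine else POSITIVE_RESIDUES
    neg = NEGATIVE_RESIDUES
    inside = seq[lo - 1 : hi]
    return ChargeCensus(
        interval=interval,
        n_positive=sum(1 for a in inside if a in pos),
        n_negative=sum(1 for a in inside if a in neg),
        total_positive=sum(1 for a in seq if a in pos),
        total_negative=sum(1 for a in seq if a in neg),
        positive_set="".join(sorted(pos)),
        negative_set="".join(sorted(neg)),
    )


_PATTERN_RE = re.compile(r"([A-Z])|\[([A-Z]+)\]")


def _compile_motif(pattern: str) -> list[frozenset[str]]:
    classes: list[frozenset[str]] = []
    pos = 0
    for m in _PATTERN_RE.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"malformed motif pattern {pattern!r}")
        classes.append(frozenset(m.group(1) or m.group(2)))
        pos = m.end()
    if pos != len(pattern) or not classes:
        raise ValueError(f"malformed motif pattern {pattern!r}")
    return classes


def find_motifs(p: ProtSeq, pattern: str = DEFAULT_MOTIF) -> list[MotifHit]:
    """All (possibly overlapping) matches of a degenerate motif pattern.

    The pattern syntax is single residue letters and bracketed residue
    classes, e.g. ``I[VL]LY[CR]``. Hits are reported left to right with
    1-based start positions.
    """
    classes = _compile_motif(pattern)
    seq = p.residues
    k = len(classes)
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if all(a in cls for a, cls in zip(window, classes)):
            hits.append(MotifHit(pattern=pattern, start_1based=i + 1, matched=window))
    return hits


def amphipathic_segments(
    profile: HydropathyProfile,
    threshold: float = 0.7,
) -> list[tuple[Interval, str]]:
    """Maximal runs of the scaled profile above/below a threshold.

    Returns ``(interval, label)`` pairs with label ``hydrophobic`` for
    windows at or above the threshold and ``hydrophilic`` below it.
    Intervals are half-open over window-center residue positions
    (0-based); adjacent same-label runs are merged by construction.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    scaled = profile.scaled
    half = profile.window // 2
    labels = ["hydrophobic" if v >= threshold else "hydrophilic" for v in scaled]
    segments: list[tuple[Interval, str]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(
                (Interval(start + half, i + half), labels[start])
            )
            start = i
    return segments


def predicted_mass_kda(p: ProtSeq) -> float:
    """Predicted average molecular mass in kDa (residues + one water).

    Average (not monoisotopic) masses, matching the SDS-PAGE gel-band
    comparison context in which these predictions are quoted.
    """
    seq = p.residues
    if not seq:
        raise ValueError("cannot compute mass of an empty protein")
    return molecular_weight(seq, seq_type="protein") / 1000.0


def feature_report(
    p: ProtSeq,
    core_interval: tuple[int, int] | None = None,
    window: int = 9,
    motif: str = DEFAULT_MOTIF,
    segment_threshold: float = 0.7,
    include_histidine: bool = False,
) -> dict:
    """JSON-ready physicochemical summary of one protein."""
    profile = kd_profile(p, window=window) if len(p.residues) >= window else None
    report: dict = {
        "id": p.id,
        "length_aa": len(p.residues),
        "predicted_mass_kda": round(predicted_mass_kda(p), 3),
        "kd_raw_mean": round(kd_raw_mean(p), 4),
        "kd_scaled_index": round(kd_index(p), 4),
        "kd_scaling": "(mean + 4.5) / 9",
        "motif_pattern": motif,
        "motifs": [
            {"start_1based": h.start_1based, "matched": h.matched}
            for h in find_motifs(p, motif)
        ],
    }
    if core_interval is not None:
        census = charge_census(p, core_interval, include_histidine)
        report["charge_census"] = {
            "interval_1based": list(census.interval),
            "n_positive_in_interval": census.n_positive,
            "n_negative_in_interval": census.n_negative,
            "total_positive": census.total_positive,
            "total_negative": census.total_negative,
            "positive_set": census.positive_set,
            "negative_set": census.negative_set,
        }
    if profile is not None:
        segments = amphipathic_segments(profile, segment_threshold)
        report["segments"] = [
            {
                "start_1based": iv.start + 1,
                "end_1based": iv.end,
                "label": label,
            }
            for iv, label in segments
        ]
    return report
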