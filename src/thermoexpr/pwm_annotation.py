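"""PWM scanning of the locus into a fixed binding-site map.

Each TF's position weight matrix is slid along both strands of the locus;
windows scoring above a per-TF normalized-score threshold, and not
overlapping closed chromatin, become :class:`BindingSite` records.  The
resulting :class:`SiteMap` is the fixed input shared by every downstream
model layer — site scores carry no positional information along the embryo
axis (they are identical for every nucleus); spatial patterning enters only
through TF concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import LocusSequence, PWMatrix

__all__ = ["BindingSite", "SiteMap", "score_window", "scan_sites"]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class BindingSite:
    """A PWM match on the locus.

    ``start``/``end`` are TSS-relative locus coordinates (half-open);
    ``score`` is the log2 likelihood-ratio score against background and
    ``norm_score`` its min–max rescaling to [0, 1] within the PWM.
    """

    tf_name: str
    start: int
    end: int
    strand: str
    score: float
    norm_score: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.norm_score <= 1.0 + 1e-12:
            raise ValueError(f"norm_score {self.norm_score} outside [0, 1]")

    @property
    def site_id(self) -> str:
        return f"{self.tf_name}@{self.start}{self.strand}"

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    def gap_to(self, other: "BindingSite") -> int:
        """Edge-to-edge distance in bp; 0 if the intervals touch or overlap."""
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass(frozen=True)
class SiteMap:
    """All accepted binding sites on one locus, in deterministic order."""

    sites: tuple[BindingSite, ...]
    locus: LocusSequence

    def __post_init__(self) -> None:
        ordered = tuple(
            sorted(self.sites, key=lambda s: (s.start, s.tf_name, s.strand))
        )
        ids = [s.site_id for s in ordered]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site ids: {dup}")
        object.__setattr__(self, "sites", ordered)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    @property
    def tf_names(self) -> list[str]:
        return sorted({s.tf_name for s in self.sites})

    def by_id(self, site_id: str) -> BindingSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def to_bed(self, path: str | Path, chrom: str = "locus") -> None:
        """Export as BED6 with the conventional 0–1000 integer score column."""
        off = self.locus.origin_offset
        with open(path, "w") as fh:
            for s in self.sites:
                score = int(min(1000, round(s.norm_score * 1000)))
                fh.write(
                    f"{chrom}\t{s.start + off}\t{s.end + off}\t"
                    f"{s.site_id}\t{score}\t{s.strand}\n"
                )


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_window(pwm: PWMatrix, subseq: str, strand: str = "+") -> float:
    """Log2-odds score of one window; ``-`` scores the reverse complement."""
    if len(subseq) != len(pwm):
        raise ValueError(
            f"window length {len(subseq)} != PWM length {len(pwm)}"
        )
    if strand == "-":
        subseq = reverse_complement(subseq)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    lo = pwm.log_odds
    total = 0.0
    for i, base in enumerate(subseq.upper()):
        if base == "N":
            raise ValueError(f"N at window position {i}; N windows are skipped upstream")
        total += lo[i, _BASE_INDEX[base]]
    return float(total)


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _scan_one(pwm: PWMatrix, locus: LocusSequence, cutoff: float) -> list[BindingSite]:
    """Above-cutoff windows of one PWM on both strands (vectorized)."""
    L = len(pwm)
    seq = locus.sequence
    n = len(seq) - L + 1
    if n <= 0:
        return []
    lo = pwm.log_odds
    smin, smax = pwm.min_score, pwm.max_score
    span = smax - smin
    codes = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)  # (n, L)
    valid = (windows >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("%s: skipped %d windows containing N", pwm.tf_name, n_skipped)
    pos = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)
    fwd = lo[pos[None, :], safe].sum(axis=1)
    rc_lo = lo[::-1, ::-1]  # scoring the reverse complement in place
    rev = rc_lo[pos[None, :], safe].sum(axis=1)
    sites: list[BindingSite] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        norm = (scores - smin) / span if span > 0 else np.ones(n)
        norm = np.clip(norm, 0.0, 1.0)
        for i in np.flatnonzero(valid & (norm >= cutoff)):
            start = locus.to_locus(int(i))
            sites.append(
                BindingSite(pwm.tf_name, start, start + L, strand,
                            float(scores[i]), float(norm[i]))
            )
    return sites


def scan_sites(
    locus: LocusSequence,
    pwms: Sequence[PWMatrix],
    threshold: float | Mapping[str, float] = 0.7,
) -> SiteMap:
    """Scan the locus with every PWM and keep accessible, high-scoring sites.

    ``threshold`` is a normalized-score cutoff in (0, 1], either one value
    for all TFs or a per-TF mapping.  Sites overlapping a closed-chromatin
    interval by at least 1 bp are removed.
    """
    if not pwms:
        raise ValueError("empty PWM list")

    def cutoff(tf: str) -> float:
        t = threshold[tf] if isinstance(threshold, Mapping) else threshold
        if not 0.0 < t <= 1.0:
            raise ValueError(f"threshold for {tf} must be in (0, 1], got {t}")
        return t

    kept: list[BindingSite] = []
    for pwm in pwms:
        for site in _scan_one(pwm, locus, cutoff(pwm.tf_name)):
            if locus.is_closed(site.start, site.end):
                continue
            kept.append(site)
    return SiteMap(tuple(kept), locus)
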