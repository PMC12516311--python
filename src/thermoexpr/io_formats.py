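"""Readers and writers for every external representation used by the model.

Sequences come in as single-record FASTA, motifs as JASPAR-style count
matrices, per-nucleus transcription-factor concentrations and expression
profiles as CSV tables keyed by percent egg length (%EL), genomic regions as
BED, and fit ensembles as JSON-lines.  All readers validate strictly and
raise :class:`FormatError` rather than silently coercing malformed input.

Coordinate convention: internally sequences are 0-based half-open on the
string index; user-facing *locus coordinates* are basepairs relative to the
transcription start site (negative = upstream).  ``LocusSequence`` owns the
conversion.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "LocusSequence",
    "PWMatrix",
    "TFProfileTable",
    "ExpressionProfile",
    "read_fasta",
    "write_fasta",
    "read_pwm",
    "write_pwm",
    "read_profiles",
    "write_profiles",
    "read_expression",
    "write_expression",
    "read_regions",
    "write_regions",
    "read_ensemble",
    "write_ensemble",
]

_VALID_BASES = set("ACGTN")
_BASES = "ACGT"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge half-open intervals; reject malformed ones."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if b <= a:
            raise FormatError(f"empty or inverted interval [{a}, {b})")
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass(frozen=True)
class LocusSequence:
    """A locus sequence with TSS-relative coordinates and an accessibility mask.

    Parameters
    ----------
    sequence
        Uppercase DNA over ``{A, C, G, T, N}``.
    origin_offset
        Integer such that ``locus coordinate = index - origin_offset``; a
        locus whose first base sits 1600 bp upstream of the TSS has
        ``origin_offset = 1600``.
    closed_regions
        Half-open ``[start, end)`` intervals, in locus coordinates, of
        chromatin that is *closed* (inaccessible to TFs).
    """

    sequence: str
    origin_offset: int = 0
    closed_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty sequence")
        seq = self.sequence.upper()
        for i, b in enumerate(seq):
            if b not in _VALID_BASES:
                raise FormatError(f"invalid base {b!r} at index {i}")
        object.__setattr__(self, "sequence", seq)
        merged = _normalize_intervals(self.closed_regions)
        lo, hi = self.locus_span
        for a, b in merged:
            if a < lo or b > hi:
                raise FormatError(
                    f"closed region [{a}, {b}) outside locus span [{lo}, {hi})"
                )
        object.__setattr__(self, "closed_regions", tuple(merged))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def locus_span(self) -> tuple[int, int]:
        """Half-open span of the locus in TSS-relative coordinates."""
        return -self.origin_offset, len(self.sequence) - self.origin_offset

    def to_locus(self, index: int) -> int:
        return index - self.origin_offset

    def to_index(self, locus_coord: int) -> int:
        return locus_coord + self.origin_offset

    def is_closed(self, start: int, end: int) -> bool:
        """True if locus-coordinate window [start, end) overlaps closed chromatin."""
        return any(start < b and a < end for a, b in self.closed_regions)


@dataclass(frozen=True)
class PWMatrix:
    """A position frequency matrix over A, C, G, T with background.

    ``matrix`` holds per-position base *frequencies* (rows sum to 1); raw
    counts are converted at read time with a pseudocount.
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 1.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise FormatError(f"PWM must be Lx4, got shape {m.shape}")
        if m.shape[0] < 4:
            raise FormatError(f"PWM length {m.shape[0]} < 4")
        if np.any(m < 0):
            raise FormatError("negative PWM entries")
        if self.pseudocount <= 0:
            raise FormatError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise FormatError("background must be 4 strictly positive frequencies summing to 1")
        rowsums = m.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise FormatError("frequency matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(
        cls,
        tf_name: str,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: np.ndarray | None = None,
    ) -> "PWMatrix":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise FormatError("negative counts")
        freq = (c + pseudocount) / (c.sum(axis=1, keepdims=True) + 4.0 * pseudocount)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(tf_name=tf_name, matrix=freq, pseudocount=pseudocount, background=bg)

    @property
    def log_odds(self) -> np.ndarray:
        """Per-position log2(p/background) scores, shape (L, 4)."""
        return np.log2(self.matrix / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))


def _check_grid(nu: np.ndarray) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    if nu.ndim != 1 or nu.size == 0:
        raise FormatError("empty nu grid")
    if np.any(~np.isfinite(nu)):
        raise FormatError("non-finite nu value")
    if np.any(np.diff(nu) <= 0):
        raise FormatError("nu grid must be strictly increasing (no duplicates)")
    return nu


@dataclass(frozen=True)
class TFProfileTable:
    """Per-nucleus TF concentration profiles along the A–P axis.

    ``nu_grid`` is in %EL; concentrations are relative fluorescence units,
    one vector per TF, all aligned to the same grid.
    """

    nu_grid: np.ndarray
    concentrations: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        nu = _check_grid(self.nu_grid)
        object.__setattr__(self, "nu_grid", nu)
        conc = {}
        for tf, v in self.concentrations.items():
            v = np.asarray(v, dtype=float)
            if v.shape != nu.shape:
                raise FormatError(f"profile for {tf} has wrong length")
            if np.any(~np.isfinite(v)):
                raise FormatError(f"NaN/inf in profile for {tf}")
            if np.any(v < 0):
                raise FormatError(f"negative concentration for {tf}")
            conc[tf] = v
        if not conc:
            raise FormatError("no TF profiles")
        object.__setattr__(self, "concentrations", conc)

    @property
    def tf_names(self) -> list[str]:
        return list(self.concentrations)

    def matrix(self, tf_order: Sequence[str]) -> np.ndarray:
        """Concentrations stacked as (n_tf, n_nu) in the given TF order."""
        return np.stack([self.concentrations[tf] for tf in tf_order])


@dataclass(frozen=True)
class ExpressionProfile:
    """An expression profile O_nu (observed) or M_nu (model) on a %EL grid."""

    nu_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        nu = _check_grid(self.nu_grid)
        v = np.asarray(self.values, dtype=float)
        if v.shape != nu.shape:
            raise FormatError("values length does not match nu grid")
        if np.any(~np.isfinite(v)):
            raise FormatError("non-finite expression value")
        object.__setattr__(self, "nu_grid", nu)
        object.__setattr__(self, "values", v)

    def window(self, lo: float, hi: float) -> "ExpressionProfile":
        """Restrict to nu in [lo, hi]."""
        mask = (self.nu_grid >= lo) & (self.nu_grid <= hi)
        if not mask.any():
            raise FormatError(f"no grid points in window [{lo}, {hi}]")
        return ExpressionProfile(self.nu_grid[mask], self.values[mask])


# ---------------------------------------------------------------------------
# FASTA

_OFFSET_RE = re.compile(r"\boffset=(-?\d+)\b")


def read_fasta(path: str | Path, closed_regions: Iterable[tuple[int, int]] = ()) -> LocusSequence:
    """Read a single-record FASTA into a :class:`LocusSequence`.

    The TSS offset is taken from an ``offset=<int>`` token in the header
    (default 0).  Multi-record files and non-ACGTN symbols are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly 1 FASTA record, found {len(records)}")
    rec = records[0]
    m = _OFFSET_RE.search(rec.description)
    offset = int(m.group(1)) if m else 0
    return LocusSequence(str(rec.seq), origin_offset=offset,
                         closed_regions=tuple(closed_regions))


def write_fasta(locus: LocusSequence, path: str | Path, name: str = "locus") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name} offset={locus.origin_offset}\n")
        seq = locus.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# JASPAR-style PWMs

_ROW_RE = re.compile(r"^([ACGT])\s*\[?\s*([-0-9. \t]+?)\s*\]?\s*$")


def read_pwm(path: str | Path, pseudocount: float = 1.0,
             background: np.ndarray | None = None) -> PWMatrix:
    """Read a JASPAR-style matrix (4 labelled rows A/C/G/T of counts).

    Counts (or frequencies) are smoothed with ``pseudocount`` per base and
    renormalized to frequencies.
    """
    name = Path(path).stem
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                parts = line[1:].split()
                name = parts[-1] if parts else name
                continue
            m = _ROW_RE.match(line)
            if not m:
                raise FormatError(f"unparseable PWM line: {line!r}")
            base, nums = m.group(1), m.group(2).split()
            vals = [float(x) for x in nums]
            if any(v < 0 for v in vals):
                raise FormatError(f"negative entry in row {base}")
            rows[base] = vals
    if set(rows) != set(_BASES):
        raise FormatError(f"expected rows A,C,G,T; found {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"row-length mismatch: {sorted(lengths)}")
    counts = np.array([[rows[b][i] for b in _BASES] for i in range(lengths.pop())])
    return PWMatrix.from_counts(name, counts, pseudocount=pseudocount,
                                background=background)


def write_pwm(pwm: PWMatrix, path: str | Path, counts_scale: float = 1e6) -> None:
    """Write as a JASPAR-style frequency matrix scaled to pseudo-counts."""
    with open(path, "w") as fh:
        fh.write(f">{pwm.tf_name} {pwm.tf_name}\n")
        for j, b in enumerate(_BASES):
            vals = " ".join(f"{v * counts_scale:.6f}" for v in pwm.matrix[:, j])
            fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# CSV tables

def read_profiles(path: str | Path) -> TFProfileTable:
    """Read a ``nu,<tf>,...`` CSV of per-nucleus TF concentrations."""
    df = pd.read_csv(path)
    if df.columns[0] != "nu":
        raise FormatError("first column must be 'nu'")
    if df.isna().any().any():
        raise FormatError("NaN in profile table")
    nu = df["nu"].to_numpy(float)
    if np.any(np.diff(nu) <= 0):
        raise FormatError("unsorted or duplicated nu values")
    conc = {c: df[c].to_numpy(float) for c in df.columns[1:]}
    return TFProfileTable(nu, conc)


def write_profiles(table: TFProfileTable, path: str | Path) -> None:
    df = pd.DataFrame({"nu": table.nu_grid, **table.concentrations})
    df.to_csv(path, index=False)


def read_expression(path: str | Path) -> ExpressionProfile:
    """Read a ``nu,value`` CSV expression profile."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["nu", "value"]:
        raise FormatError("expression CSV must have columns nu,value")
    if df.isna().any().any():
        raise FormatError("NaN in expression table")
    nu = df["nu"].to_numpy(float)
    if np.any(np.diff(nu) <= 0):
        raise FormatError("unsorted or duplicated nu values")
    return ExpressionProfile(nu, df["value"].to_numpy(float))


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    pd.DataFrame({"nu": profile.nu_grid, "value": profile.values}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# BED regions

def read_regions(path: str | Path, origin_offset: int = 0) -> list[tuple[int, int, str]]:
    """Read BED (3+ columns, 0-based half-open) into locus-coordinate intervals.

    ``origin_offset`` shifts sequence-index coordinates to TSS-relative
    locus coordinates: ``locus = bed_coord - origin_offset``.
    """
    out: list[tuple[int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"BED line {ln}: fewer than 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise FormatError(f"BED line {ln}: non-integer coordinate") from e
            if end <= start:
                raise FormatError(f"BED line {ln}: empty interval")
            name = cols[3] if len(cols) > 3 else f"region{ln}"
            out.append((start - origin_offset, end - origin_offset, name))
    return out


def write_regions(regions: Iterable[tuple[int, int, str]], path: str | Path,
                  chrom: str = "locus", origin_offset: int = 0) -> None:
    with open(path, "w") as fh:
        for start, end, name in regions:
            fh.write(f"{chrom}\t{start + origin_offset}\t{end + origin_offset}\t{name}\n")


# ---------------------------------------------------------------------------
# Fit-ensemble JSON-lines

def _fit_to_dict(fit) -> dict:
    d = {
        "params": dict(fit.params),
        "rms": fit.rms,
        "predicted": {
            "nu": list(map(float, fit.predicted.nu_grid)),
            "value": list(map(float, fit.predicted.values)),
        },
        "seed": fit.seed,
        "round_id": fit.round_id,
        "filter1_pass": fit.filter1_pass,
        "filter2_pass": fit.filter2_pass,
    }
    return d


def write_ensemble(fits: Sequence, path: str | Path) -> None:
    """Write a list of FitResult as JSON-lines (lossless round trip)."""
    with open(path, "w") as fh:
        for fit in fits:
            fh.write(json.dumps(_fit_to_dict(fit)) + "\n")


def read_ensemble(path: str | Path) -> list:
    from .annealing_fit import FitResult
    from .thermo_model import ParameterSet

    fits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            fits.append(
                FitResult(
                    params=ParameterSet(d["params"]),
                    rms=float(d["rms"]),
                    predicted=ExpressionProfile(
                        np.array(d["predicted"]["nu"]),
                        np.array(d["predicted"]["value"]),
                    ),
                    seed=int(d["seed"]),
                    round_id=int(d["round_id"]),
                    filter1_pass=d.get("filter1_pass"),
                    filter2_pass=d.get("filter2_pass"),
                )
            )
    return fits
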