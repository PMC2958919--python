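"""Compositional-heterogeneity diagnostics on codon-partitioned alignments.

Nonstationary base composition violates the assumptions of standard
time-reversible tree inference and can produce artefactual groupings.  Two
diagnostics are provided: the classical chi-square homogeneity test of base
counts across taxa (which ignores phylogenetic correlation) and the
matched-pairs (Bowker) test of symmetry on each pair of sequences' 4x4
site-pattern table, plus RY recoding to purines/pyrimidines, the usual
remedy for third-position heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io_formats import Alignment

__all__ = [
    "ChisqResult",
    "SymmetryResult",
    "composition_chisq",
    "bowker_pairs",
    "bowker_statistic",
    "ry_recode",
]


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    counts: pd.DataFrame


@dataclass
class SymmetryResult:
    """Pairwise Bowker tests and the share of significant pairs per class."""

    pairs: pd.DataFrame            # taxon_a, taxon_b, statistic, df, p_value
    percent_significant: float     # over pairs with comparable sites
    alpha: float = 0.05
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


def _select_columns(a: Alignment, positions: Iterable[int] | int | None) -> list[int]:
    if positions is None:
        return list(range(a.n_sites))
    if isinstance(positions, int):
        positions = [positions]
    cols: list[int] = []
    for p in positions:
        cols.extend(a.codon_positions(p))
    return sorted(set(cols))


def _state_set(chars: np.ndarray) -> list[str]:
    """Counted states: A/C/G/T normally; R/Y for fully recoded columns."""
    present = set(chars.ravel().tolist())
    if present & set("ACGT"):
        return list("ACGT")
    return ["R", "Y"]


def composition_chisq(
    a: Alignment, positions: Iterable[int] | int | None = None
) -> ChisqResult:
    """Chi-square homogeneity test of base counts across taxa.

    Gaps and ambiguity codes are excluded from the counts; taxa with no
    counted sites in the selected columns are dropped with a warning.
    Expected counts come from the pooled composition; df =
    (taxa − 1) · (states − 1), i.e. (taxa − 1)·3 for nucleotides and
    (taxa − 1)·1 after RY recoding.
    """
    cols = _select_columns(a, positions)
    if not cols:
        raise ValueError("no alignment columns selected")
    M = a.to_array()[:, cols]
    states = _state_set(M)
    counts = np.stack([(M == s).sum(axis=1) for s in states], axis=1).astype(float)
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        dropped = [t for t, k in zip(a.taxon_ids, keep) if not k]
        warnings.warn(f"taxa with no counted sites excluded: {dropped}")
    counts = counts[keep]
    taxa = [t for t, k in zip(a.taxon_ids, keep) if k]
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa with counted sites")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    df = (len(taxa) - 1) * (len(states) - 1)
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    table = pd.DataFrame(counts, index=taxa, columns=states)
    return ChisqResult(stat, df, p, table)


def bowker_statistic(table: np.ndarray) -> tuple[float, int, float]:
    """Bowker's test of symmetry on a square site-pattern table.

    statistic = sum over state pairs i<j with n_ij + n_ji > 0 of
    (n_ij − n_ji)² / (n_ij + n_ji); df = the number of such pairs; the
    p-value is the chi-square upper tail (1 when df = 0).
    """
    t = np.asarray(table, dtype=float)
    if t.shape[0] != t.shape[1]:
        raise ValueError("site-pattern table must be square")
    stat = 0.0
    df = 0
    m = t.shape[0]
    for i in range(m):
        for j in range(i + 1, m):
            s = t[i, j] + t[j, i]
            if s > 0:
                stat += (t[i, j] - t[j, i]) ** 2 / s
                df += 1
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), df, p


def bowker_pairs(
    a: Alignment,
    positions: Iterable[int] | int | None = None,
    alpha: float = 0.05,
) -> SymmetryResult:
    """Matched-pairs tests of symmetry for every pair of taxa.

    For each pair, the site-pattern table is built over columns where both
    sequences have unambiguous states (pairwise, not listwise, deletion);
    pairs with no comparable site are flagged and excluded from the
    percentage of significant pairs.
    """
    cols = _select_columns(a, positions)
    if not cols:
        raise ValueError("no alignment columns selected")
    M = a.to_array()[:, cols]
    states = _state_set(M)
    index = {s: i for i, s in enumerate(states)}
    codes = np.full(M.shape, -1, dtype=np.int8)
    for s, i in index.items():
        codes[M == s] = i
    n_taxa = len(a.taxon_ids)
    rows = []
    excluded: list[tuple[str, str]] = []
    n_sig = 0
    n_used = 0
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            if not both.any():
                excluded.append((a.taxon_ids[i], a.taxon_ids[j]))
                continue
            table = np.zeros((len(states), len(states)))
            np.add.at(table, (codes[i][both], codes[j][both]), 1.0)
            stat, df, p = bowker_statistic(table)
            rows.append(dict(
                taxon_a=a.taxon_ids[i], taxon_b=a.taxon_ids[j],
                statistic=stat, df=df, p_value=p,
            ))
            n_used += 1
            if p < alpha:
                n_sig += 1
    pct = 100.0 * n_sig / n_used if n_used else float("nan")
    return SymmetryResult(pd.DataFrame(rows), pct, alpha, excluded)


_RY = {"A": "R", "G": "R", "C": "Y", "T": "Y", "-": "-"}


def ry_recode(a: Alignment, positions: Iterable[int] | int | None = None) -> Alignment:
    """Pool purines (A, G → R) and pyrimidines (C, T → Y) at the selected
    codon positions; gaps are preserved, other symbols become N, unselected
    positions are unchanged."""
    cols = set(_select_columns(a, positions))
    out = []
    for seq in a.sequences:
        chars = list(seq)
        for c in cols:
            ch = chars[c]
            chars[c] = _RY.get(ch, "R" if ch == "R" else "Y" if ch == "Y" else "N")
        out.append("".join(chars))
    return Alignment(list(a.taxon_ids), out, a.frame_offset)
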