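"""Barcode dataset filtering and diversity/divergence statistics.

Implements the standard estimators reported in COI barcoding surveys:

* haplotype number k and polymorphic site count S,
* haplotype diversity ``H = n(1 - sum p_i^2)/(n - 1)`` with Nei's (1987)
  sampling variance,
* nucleotide diversity (mean pairwise differences per compared site)
  with a seeded bootstrap standard deviation,
* uncorrected p-distances and Kimura 2-parameter distances,
* per-species intra/interspecific divergence summaries with a
  conspecificity screen.

Gap/N policy: columns containing any gap or N are dropped for haplotype
collapsing, S and pi (complete deletion); p/K2P distances drop
non-comparable sites per pair (pairwise deletion).  Both policies follow
the common Arlequin/MEGA defaults.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mitobarcode.seqio import Alignment, SequenceRecord

_BASES = frozenset("ACGT")
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


# ---------------------------------------------------------------------------
# dataset filtering


@dataclass
class FilterReport:
    """Counts of records removed per filtering rule."""

    removed_rank: int = 0
    removed_length: int = 0
    removed_group_size: int = 0
    kept: int = 0

    @property
    def removed_total(self) -> int:
        return self.removed_rank + self.removed_length + self.removed_group_size


#: labels that are not identified to species level
_RANKLESS = re.compile(r"(^|[\s_])(sp\.?|cf\.?|aff\.?|nr\.?)($|[\s_])", re.IGNORECASE)


def is_species_level(label: str) -> bool:
    return bool(label.strip()) and not _RANKLESS.search(label)


def filter_barcode_dataset(
    records: list[SequenceRecord],
    min_len: int = 500,
    min_per_species: int = 3,
    require_species_level: bool = True,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Apply the survey filtering rules in order.

    1. drop records without a species-level label (``sp.``/``cf.`` etc.)
       unless ``require_species_level`` is False;
    2. drop records with ungapped length < ``min_len``;
    3. drop species left with fewer than ``min_per_species`` records.

    Input order is preserved; an empty result is legal.
    """
    report = FilterReport()
    stage1: list[SequenceRecord] = []
    for rec in records:
        if require_species_level and not is_species_level(rec.species):
            report.removed_rank += 1
        else:
            stage1.append(rec)
    stage2: list[SequenceRecord] = []
    for rec in stage1:
        if rec.ungapped_length < min_len:
            report.removed_length += 1
        else:
            stage2.append(rec)
    counts: dict[str, int] = {}
    for rec in stage2:
        counts[rec.species] = counts.get(rec.species, 0) + 1
    kept = [r for r in stage2 if counts[r.species] >= min_per_species]
    report.removed_group_size = len(stage2) - len(kept)
    report.kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts and member ids.

    ``haplotypes`` holds (collapsed sequence over compared columns,
    count, member ids); invariants: sum of counts = n, k <= n.
    """

    haplotypes: list[tuple[str, int, list[str]]]
    n: int
    compared_columns: list[int]

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [c for _, c, _ in self.haplotypes]

    @property
    def freqs(self) -> np.ndarray:
        return np.array(self.counts, dtype=float) / self.n


def comparable_columns(aln: Alignment) -> list[int]:
    """Columns where every sequence carries a plain A/C/G/T base."""
    cols = []
    for j in range(aln.length):
        if all(rec.seq[j] in _BASES for rec in aln.records):
            cols.append(j)
    return cols


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group sequences identical at all compared columns.

    Complete deletion: columns containing any gap or N in any sequence
    are excluded from the comparison.  Raises if no column survives.
    """
    cols = comparable_columns(aln)
    if not cols:
        raise ValueError("no comparable sites: every column has a gap or N")
    groups: dict[str, list[str]] = {}
    for rec in aln.records:
        key = "".join(rec.seq[j] for j in cols)
        groups.setdefault(key, []).append(rec.id)
    haplotypes = [(seq, len(ids), ids) for seq, ids in groups.items()]
    return HaplotypeTable(haplotypes=haplotypes, n=len(aln.records),
                          compared_columns=cols)


def haplotype_diversity(tab: HaplotypeTable) -> tuple[float, float] | None:
    """(H, SD) with the n/(n-1) small-sample correction.

    H is the probability that two distinct sampled individuals carry
    different haplotypes; the SD comes from Nei's (1987) variance
    estimator.  Returns None (reported "n.a.") for n < 2 or a
    monomorphic sample.
    """
    n = tab.n
    if n < 2:
        return None
    p = tab.freqs
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n * (1.0 - sum2) / (n - 1)
    if tab.k == 1:
        return None
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2
    )
    return h, math.sqrt(max(var, 0.0))


def segregating_sites(aln: Alignment) -> int:
    """Number of compared columns with more than one nucleotide state."""
    cols = comparable_columns(aln)
    s = 0
    for j in cols:
        if len({rec.seq[j] for rec in aln.records}) > 1:
            s += 1
    return s


def nucleotide_diversity(
    aln: Alignment,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """(pi, SD): mean pairwise differences per compared site.

    Complete deletion of gap/N columns.  The SD is a seeded
    nonparametric bootstrap over sequences (resampling rows, keeping the
    column set fixed), a deliberate divergence from Arlequin's analytic
    total-variance estimator.
    """
    cols = comparable_columns(aln)
    if not cols:
        raise ValueError("no comparable sites: every column has a gap or N")
    n = len(aln.records)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    mat = np.array([[rec.seq[j] for j in cols] for rec in aln.records])

    def _pi(rows: np.ndarray) -> float:
        m = rows.shape[0]
        total = 0
        for i in range(m):
            for j in range(i + 1, m):
                total += int(np.sum(rows[i] != rows[j]))
        return total / (m * (m - 1) / 2) / len(cols)

    pi = _pi(mat)
    if bootstrap_reps <= 0:
        return pi, 0.0
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        reps[b] = _pi(mat[idx])
    return pi, float(np.std(reps, ddof=1))


@dataclass
class DiversitySummary:
    """Per-species row of a Table-1-style genetic diversity summary."""

    species: str
    n: int
    k: int
    S: int
    H: float | None
    H_sd: float | None
    pi: float | None
    pi_sd: float | None


def diversity_summary(
    aln: Alignment,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> DiversitySummary:
    """All diversity statistics for one species' alignment."""
    species = aln.records[0].species
    tab = collapse_haplotypes(aln)
    s = segregating_sites(aln)
    hd = haplotype_diversity(tab)
    if len(aln.records) >= 2:
        pi, pi_sd = nucleotide_diversity(aln, bootstrap_reps, seed)
        if tab.k == 1:
            pi = pi_sd = None  # monomorphic: printed n.a. alongside H
    else:
        pi = pi_sd = None
    return DiversitySummary(
        species=species, n=tab.n, k=tab.k, S=s,
        H=None if hd is None else hd[0],
        H_sd=None if hd is None else hd[1],
        pi=pi, pi_sd=pi_sd,
    )


# ---------------------------------------------------------------------------
# pairwise distances


def _comparable_pair(a: str, b: str) -> list[tuple[str, str]]:
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    return [(x, y) for x, y in zip(a, b) if x in _BASES and y in _BASES]


def p_distance(a: str, b: str) -> float | None:
    """Proportion of differing comparable sites (pairwise deletion).

    None when no site is comparable.
    """
    pairs = _comparable_pair(a, b)
    if not pairs:
        return None
    diffs = sum(1 for x, y in pairs if x != y)
    return diffs / len(pairs)


def transition_transversion_proportions(a: str, b: str) -> tuple[float, float] | None:
    """(P, Q): transition and transversion proportions over comparable sites."""
    pairs = _comparable_pair(a, b)
    if not pairs:
        return None
    ts = tv = 0
    for x, y in pairs:
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts / len(pairs), tv / len(pairs)


def k2p_distance(a: str, b: str) -> float | None:
    """Kimura 2-parameter distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    None when no site is comparable or the correction is saturated
    (log argument non-positive); saturation is flagged by the caller
    via :func:`distance_matrix`.
    """
    pq = transition_transversion_proportions(a, b)
    if pq is None:
        return None
    p_ts, q_tv = pq
    w1 = 1.0 - 2.0 * p_ts - q_tv
    w2 = 1.0 - 2.0 * q_tv
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined entries as NaN."""

    ids: list[str]
    d: np.ndarray
    model: str  # "p" | "K2P"

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if math.isnan(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def distance_matrix(aln: Alignment, model: str = "K2P") -> DistanceMatrix:
    """All pairwise distances under the chosen model (undefined -> NaN)."""
    if model not in ("p", "K2P"):
        raise ValueError(f"unknown distance model {model!r}")
    fn = p_distance if model == "p" else k2p_distance
    n = len(aln.records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            val = fn(aln.records[i].seq, aln.records[j].seq)
            d[i, j] = d[j, i] = math.nan if val is None else val
    return DistanceMatrix(ids=[r.id for r in aln.records], d=d, model=model)


# ---------------------------------------------------------------------------
# divergence summaries


@dataclass
class DivergenceSummary:
    """Intra/interspecific divergence tables plus a conspecificity screen.

    Distances are proportions; the conspecificity threshold is on the
    same scale (default 0.03 = 3%, with 2-3% reported as a warning
    zone).  Species whose intraspecific maximum exceeds the threshold
    are flagged as potential misidentification or cryptic diversity.
    """

    intra: pd.DataFrame  # species, n_pairs, mean, max, flagged, warn_zone
    inter: pd.DataFrame  # species_a, species_b, n_pairs, min, max, mean
    model: str
    threshold: float
    n_undefined: int = 0

    @property
    def flagged_species(self) -> list[str]:
        return list(self.intra.loc[self.intra["flagged"], "species"])

    def barcode_gap(self) -> bool:
        """True when every interspecific distance exceeds every
        intraspecific distance (global gap)."""
        if self.intra.empty or self.inter.empty:
            return False
        return float(self.inter["min"].min()) > float(self.intra["max"].max())


def divergence_summary(
    aln: Alignment,
    model: str = "K2P",
    threshold: float = 0.03,
    warn_band: tuple[float, float] = (0.02, 0.03),
) -> DivergenceSummary:
    """Per-species max/mean intra- and pairwise min/max interspecific
    distances, with the conspecificity screen."""
    dm = distance_matrix(aln, model)
    labels = [r.species for r in aln.records]
    species = sorted(set(labels))
    n_undef = 0

    intra_rows = []
    for sp in species:
        idx = [i for i, s in enumerate(labels) if s == sp]
        vals = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                v = dm.d[idx[a], idx[b]]
                if math.isnan(v):
                    n_undef += 1
                else:
                    vals.append(v)
        if not vals:
            continue
        mx = max(vals)
        intra_rows.append({
            "species": sp, "n_pairs": len(vals),
            "mean": float(np.mean(vals)), "max": mx,
            "flagged": mx > threshold,
            "warn_zone": warn_band[0] <= mx <= warn_band[1],
        })

    inter_rows = []
    for i, sa in enumerate(species):
        for sb in species[i + 1:]:
            ia = [k for k, s in enumerate(labels) if s == sa]
            ib = [k for k, s in enumerate(labels) if s == sb]
            vals = []
            for a in ia:
                for b in ib:
                    v = dm.d[a, b]
                    if math.isnan(v):
                        n_undef += 1
                    else:
                        vals.append(v)
            if not vals:
                continue
            inter_rows.append({
                "species_a": sa, "species_b": sb, "n_pairs": len(vals),
                "min": min(vals), "max": max(vals),
                "mean": float(np.mean(vals)),
            })

    intra = pd.DataFrame(intra_rows, columns=["species", "n_pairs", "mean",
                                              "max", "flagged", "warn_zone"])
    inter = pd.DataFrame(inter_rows, columns=["species_a", "species_b",
                                              "n_pairs", "min", "max", "mean"])
    return DivergenceSummary(intra=intra, inter=inter, model=model,
                             threshold=threshold, n_undefined=n_undef)
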