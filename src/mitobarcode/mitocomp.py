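"""Comparative mitogenome statistics.

Descriptive statistics of annotated circular mitogenomes:

* nucleotide composition with AT skew = (A-T)/(A+T) and
  GC skew = (G-C)/(G+C), per feature and aggregated;
* start/stop codon classification under the invertebrate mitochondrial
  genetic code (NCBI translation table 5), including the incomplete
  stop codons ("TA", "T") completed by post-transcriptional
  polyadenylation;
* relative synonymous codon usage (RSCU);
* gene overlap / intergenic spacer accounting with circular closure;
* Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction and
  equal-weight pathway averaging for multi-hit codons;
* a deterministic exhaustive-scan tandem-repeat detector for the
  AT-rich (control) region.

Strand convention: N-strand features are analyzed on their reverse
complement for codon work, but composition/skew aggregates are offered
in both gene-native and published-strand (J) orientations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from mitobarcode.seqio import MitoAnnotation, reverse_complement

INVERTEBRATE_MITO_TABLE = 5


def codon_table(table_id: int = INVERTEBRATE_MITO_TABLE) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def stop_codons(table_id: int = INVERTEBRATE_MITO_TABLE) -> frozenset[str]:
    return frozenset(codon_table(table_id).stop_codons)


def translate_codon(codon: str, table_id: int = INVERTEBRATE_MITO_TABLE) -> str:
    """Single-letter amino acid, '*' for stop."""
    tab = codon_table(table_id)
    if codon in tab.stop_codons:
        return "*"
    return tab.forward_table[codon]


def synonymous_families(table_id: int = INVERTEBRATE_MITO_TABLE) -> dict[str, list[str]]:
    """Amino acid -> sorted list of its codons (stops excluded)."""
    tab = codon_table(table_id)
    fam: dict[str, list[str]] = {}
    for codon, aa in tab.forward_table.items():
        fam.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in fam.items()}


# ---------------------------------------------------------------------------
# composition and skews


@dataclass
class CompositionReport:
    """Base composition of one region with strand skews.

    Skews are None (undefined) when the denominator is zero — never
    silently reported as 0.
    """

    label: str
    length: int
    counts: dict[str, int]
    at_content: float
    at_skew: float | None
    gc_skew: float | None


def composition_and_skew(seq: str, label: str = "") -> CompositionReport:
    if not seq:
        raise ValueError(f"{label or 'region'}: empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    counts["other"] = len(seq) - sum(counts[b] for b in "ACGT")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    at_skew = (a - t) / (a + t) if a + t else None
    gc_skew = (g - c) / (g + c) if g + c else None
    return CompositionReport(
        label=label, length=len(seq), counts=counts,
        at_content=(a + t) / len(seq), at_skew=at_skew, gc_skew=gc_skew,
    )


def per_feature_composition(
    ann: MitoAnnotation,
    strand_native: bool = True,
) -> list[CompositionReport]:
    """Composition report per feature plus aggregate rows.

    Aggregates: whole genome, all PCGs, all tRNAs, all rRNAs, and the
    AT-rich region.  ``strand_native`` analyzes N-strand features on
    their reverse complement (the gene-native convention); False keeps
    the published J-strand representation throughout.
    """
    L = ann.genome_length
    reports = []
    for f in ann.features:
        if f.length(L) <= 0 or f.start >= L or f.end > L:
            raise ValueError(f"feature {f.name} out of genome bounds")
        reports.append(composition_and_skew(
            f.extract(ann.seq, strand_native=strand_native), f.name))
    reports.append(composition_and_skew(ann.seq, "genome"))
    for ftype, label in (("PCG", "all-PCG"), ("tRNA", "all-tRNA"),
                         ("rRNA", "all-rRNA"), ("control", "AT-rich-region")):
        feats = ann.by_type(ftype)
        if feats:
            concat = "".join(f.extract(ann.seq, strand_native=strand_native)
                             for f in feats)
            reports.append(composition_and_skew(concat, label))
    return reports


# ---------------------------------------------------------------------------
# start/stop codon classification


@dataclass
class CodonClassification:
    gene: str
    start_codon: str
    start_class: str       # "canonical-ATN" | "alternative"
    stop: str              # "TAA"/"TAG" or incomplete "TA"/"T"
    stop_complete: bool
    internal_stops: int
    codon_count: int
    anomaly: str = ""      # e.g. trailing residue inconsistent with T/TA


def classify_start_stop(cds: str, gene: str = "",
                        table_id: int = INVERTEBRATE_MITO_TABLE) -> CodonClassification:
    """Classify the start and (possibly incomplete) stop codon of a CDS.

    A CDS whose length is not a multiple of 3 is taken to end in an
    incomplete stop: 2 trailing bases must be "TA", 1 trailing base
    must be "T" (completed to TAA by polyadenylation); anything else is
    flagged as an anomaly rather than silently accepted.
    """
    cds = cds.upper()
    if len(cds) < 4:
        raise ValueError(f"{gene or 'CDS'}: too short to classify ({len(cds)} bp)")
    stops = stop_codons(table_id)
    start = cds[:3]
    start_class = "canonical-ATN" if start.startswith("AT") else "alternative"
    rem = len(cds) % 3
    anomaly = ""
    if rem == 0:
        stop = cds[-3:]
        complete = stop in stops
        if not complete:
            anomaly = f"final codon {stop} is not a stop codon"
        body = cds[3:-3]
    else:
        tail = cds[-rem:]
        expected = "TA" if rem == 2 else "T"
        stop = tail
        complete = False
        if tail != expected:
            anomaly = (f"trailing {tail!r} inconsistent with incomplete-stop "
                       f"convention (expected {expected!r})")
        body = cds[3: len(cds) - rem]
    internal = sum(1 for i in range(0, len(body) - 2, 3)
                   if body[i:i + 3] in stops)
    return CodonClassification(
        gene=gene, start_codon=start, start_class=start_class,
        stop=stop, stop_complete=complete, internal_stops=internal,
        codon_count=len(cds) // 3,
        anomaly=anomaly,
    )


# ---------------------------------------------------------------------------
# RSCU


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU values.

    RSCU(c) = count(c) / mean count over c's synonymous family; 1.0
    under uniform usage; the sum over a family equals its degeneracy.
    Stop codons are excluded from families; single-codon families have
    RSCU identically 1 when observed, None when never observed.
    """

    table: pd.DataFrame  # columns: codon, amino_acid, count, degeneracy, rscu

    def rscu_of(self, codon: str) -> float | None:
        row = self.table.loc[self.table["codon"] == codon.upper().replace("U", "T")]
        if row.empty:
            raise KeyError(codon)
        v = row["rscu"].iloc[0]
        return None if pd.isna(v) else float(v)


def count_codons(cds_set: Iterable[str]) -> dict[str, int]:
    """Codon counts over complete in-frame codons of each CDS (a trailing
    incomplete codon is ignored)."""
    counts: dict[str, int] = {}
    for cds in cds_set:
        cds = cds.upper()
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i:i + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def rscu(cds_set: Sequence[str], table_id: int = INVERTEBRATE_MITO_TABLE,
         exclude_terminal_stop: bool = True) -> CodonUsageTable:
    """Relative synonymous codon usage over a set of coding sequences."""
    counts = count_codons(cds_set)
    if not counts:
        raise ValueError("no complete codons in input")
    stops = stop_codons(table_id)
    rows = []
    for aa, family in sorted(synonymous_families(table_id).items()):
        fam_counts = [counts.get(c, 0) for c in family]
        total = sum(fam_counts)
        mean = total / len(family) if total else 0.0
        for codon, cnt in zip(family, fam_counts):
            rows.append({
                "codon": codon, "amino_acid": aa, "count": cnt,
                "degeneracy": len(family),
                "rscu": (cnt / mean) if total else math.nan,
            })
    if not exclude_terminal_stop:
        for codon in sorted(stops):
            rows.append({"codon": codon, "amino_acid": "*",
                         "count": counts.get(codon, 0),
                         "degeneracy": len(stops), "rscu": math.nan})
    return CodonUsageTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# overlaps and spacers


@dataclass
class SpacingReport:
    """Adjacent-feature spacing with circular closure.

    Each consecutive pair (features sorted by start, plus the wrap pair
    last -> first) is exactly one of abutting / overlapping / spaced.
    """

    pairs: pd.DataFrame  # upstream, downstream, overlap, spacer
    n_overlaps: int
    n_spacers: int
    total_overlap_bp: int
    total_spacer_bp: int
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_spacer_bp(self) -> float:
        return self.total_spacer_bp / self.n_spacers if self.n_spacers else 0.0

    def longest_overlap(self) -> tuple[str, str, int] | None:
        if self.n_overlaps == 0:
            return None
        row = self.pairs.loc[self.pairs["overlap"].idxmax()]
        return str(row["upstream"]), str(row["downstream"]), int(row["overlap"])


def spacing_and_overlaps(ann: MitoAnnotation) -> SpacingReport:
    """Overlap/spacer lengths between consecutive features on the circle."""
    feats = sorted(ann.features, key=lambda f: (f.start, f.end))
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    L = ann.genome_length
    rows = []
    warnings: list[str] = []
    for prev, nxt in zip(feats, feats[1:] + feats[:1]):
        prev_end = prev.end if not prev.wraps else prev.end + L
        nxt_start = nxt.start
        if nxt is feats[0]:  # circular closure across the origin
            nxt_start += L
        overlap = max(0, prev_end - nxt_start)
        spacer = max(0, nxt_start - prev_end)
        if overlap >= nxt.length(L):
            warnings.append(f"{nxt.name} nested inside {prev.name}")
        rows.append({"upstream": prev.name, "downstream": nxt.name,
                     "overlap": overlap, "spacer": spacer})
    df = pd.DataFrame(rows)
    ov = df[df["overlap"] > 0]
    sp = df[df["spacer"] > 0]
    return SpacingReport(
        pairs=df, n_overlaps=len(ov), n_spacers=len(sp),
        total_overlap_bp=int(ov["overlap"].sum()),
        total_spacer_bp=int(sp["spacer"].sum()),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks


@dataclass
class KaKsResult:
    gene: str
    ka: float | None
    ks: float | None
    ratio: float | None
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    saturated: bool = False


def _syn_fraction(codon: str, pos: int, table_id: int) -> float:
    """Fraction of the three mutations at ``pos`` that are synonymous.

    Mutations creating a stop codon count as nonsynonymous (original
    Nei-Gojobori convention), keeping S + N = 3 per codon exactly.
    """
    stops = stop_codons(table_id)
    aa = translate_codon(codon, table_id)
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        mut = codon[:pos] + b + codon[pos + 1:]
        if mut in stops:
            continue
        if translate_codon(mut, table_id) == aa:
            syn += 1
    return syn / 3.0


def codon_sites(codon: str, table_id: int = INVERTEBRATE_MITO_TABLE) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    s = sum(_syn_fraction(codon, pos, table_id) for pos in range(3))
    return s, 3.0 - s


def codon_path_diffs(c1: str, c2: str,
                     table_id: int = INVERTEBRATE_MITO_TABLE) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-hit codons average with equal weight over all substitution
    orderings; pathways passing through a stop codon are excluded
    (falling back to all pathways if every one hits a stop).  The two
    counts sum to the Hamming distance of the codons.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0
    stops = stop_codons(table_id)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops:
                return None
            if translate_codon(cur, table_id) == translate_codon(nxt, table_id):
                s += 1
            else:
                n += 1
            cur = nxt
        return s, n

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        # every pathway crosses a stop; average over all orderings,
        # scoring the stop-crossing steps as nonsynonymous
        valid = []
        for order in itertools.permutations(diff_pos):
            cur = c1
            s = n = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                a1 = "*" if cur in stops else translate_codon(cur, table_id)
                a2 = "*" if nxt in stops else translate_codon(nxt, table_id)
                if a1 == a2:
                    s += 1
                else:
                    n += 1
                cur = nxt
            valid.append((s, n))
    s_mean = sum(p[0] for p in valid) / len(valid)
    n_mean = sum(p[1] for p in valid) / len(valid)
    return s_mean, n_mean


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance -3/4 ln(1 - 4p/3); None at saturation."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori_kaks(cds_a: str, cds_b: str, gene: str = "",
                      table_id: int = INVERTEBRATE_MITO_TABLE) -> KaKsResult:
    """Ka/Ks between two aligned coding sequences (Nei-Gojobori 1986,
    Jukes-Cantor correction).

    Sequences must be equal length; codons containing a gap in either
    sequence are dropped pairwise; internal stop codons are rejected.
    At saturation (ps or pn >= 0.75) the uncorrected proportion is
    returned with ``saturated`` set.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"{gene or 'pair'}: unequal CDS lengths")
    usable = len(a) - len(a) % 3
    stops = stop_codons(table_id)
    pairs: list[tuple[str, str]] = []
    for i in range(0, usable, 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if not (set(ca) <= set("ACGT") and set(cb) <= set("ACGT")):
            continue  # gapped/ambiguous codon dropped pairwise
        if i + 3 < usable and (ca in stops or cb in stops):
            raise ValueError(f"{gene or 'pair'}: internal stop codon at {i + 1}")
        if ca in stops or cb in stops:
            continue  # terminal stop excluded from site counting
        pairs.append((ca, cb))
    if not pairs:
        raise ValueError(f"{gene or 'pair'}: no comparable codons")

    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for ca, cb in pairs:
        sa, na = codon_sites(ca, table_id)
        sb, nb = codon_sites(cb, table_id)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        sd, ndf = codon_path_diffs(ca, cb, table_id)
        s_diffs += sd
        n_diffs += ndf

    ps = s_diffs / s_sites if s_sites else 0.0
    pn = n_diffs / n_sites if n_sites else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = ks is None or ka is None
    if ks is None:
        ks = ps
    if ka is None:
        ka = pn
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(gene=gene, ka=ka, ks=ks, ratio=ratio,
                      s_sites=s_sites, n_sites=n_sites,
                      s_diffs=s_diffs, n_diffs=n_diffs, saturated=saturated)


# ---------------------------------------------------------------------------
# tandem repeats


@dataclass
class TandemRepeat:
    motif: str
    motif_length: int
    copies: float
    start: int            # 0-based position of the first copy
    spacer: int           # bp between consecutive copies (0 = adjacent)
    coverage: float       # fraction of the scanned region covered
    identity: float       # mean pairwise identity between copies


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def find_tandem_repeats(
    region: str,
    min_motif: int = 20,
    max_motif: int = 300,
    min_copies: int = 2,
    min_identity: float = 0.9,
    max_spacer: int = 10,
) -> list[TandemRepeat]:
    """Exhaustive deterministic scan for tandem repeat arrays.

    For every motif length m in [min_motif, max_motif] and every start,
    successive windows of length m (allowing up to ``max_spacer`` bp
    between copies) are accepted while their identity to the first copy
    is >= ``min_identity``.  Overlapping reports are reduced to maximal
    arrays; arrays are returned largest-coverage first, smallest motif
    first on ties.  This is a simplified deterministic detector, not a
    reimplementation of Tandem Repeats Finder's probabilistic model.
    """
    region = region.upper()
    L = len(region)
    if L < 2 * min_motif:
        return []
    arr = np.frombuffer(region.encode("ascii"), dtype="S1")
    candidates: list[TandemRepeat] = []
    for m in range(min_motif, min(max_motif, L // 2) + 1):
        # vectorized seed detection: identity of every window against
        # the window one period (m + spacer) downstream
        seed_starts: set[int] = set()
        for sp in range(0, max_spacer + 1):
            step = m + sp
            if step + m > L:
                break
            eq = (arr[: L - step] == arr[step:]).astype(np.int32)
            win = np.convolve(eq, np.ones(m, dtype=np.int32), mode="valid") / m
            # win[s] = identity(region[s:s+m], region[s+step:s+step+m])
            seed_starts.update(int(s) for s in np.nonzero(win >= min_identity)[0])
        for start in sorted(seed_starts):
            motif = region[start: start + m]
            copies = 1
            idents: list[float] = []
            spacer_used = 0
            score = 0  # matches - mismatches over all copy comparisons
            pos = start + m
            while True:
                hit = None
                for sp in range(0, max_spacer + 1):
                    nxt = region[pos + sp: pos + sp + m]
                    if len(nxt) < m:
                        break
                    ident = _identity(motif, nxt)
                    if ident >= min_identity:
                        hit = (sp, ident)
                        break  # smallest spacer wins
                if hit is None:
                    break
                sp, ident = hit
                copies += 1
                idents.append(ident)
                spacer_used = max(spacer_used, sp)
                score += round(ident * m) - (m - round(ident * m))
                pos += sp + m
            if copies >= min_copies:
                candidates.append((score, TandemRepeat(
                    motif=motif, motif_length=m, copies=float(copies),
                    start=start, spacer=spacer_used,
                    coverage=min(copies * m / L, 1.0),
                    identity=float(np.mean(idents)) if idents else 1.0,
                )))
    if not candidates:
        return []
    # reduce overlapping reports: rank by alignment score (+1 match,
    # -1 mismatch, so sliding a window off the true phase never
    # gains), smallest motif and earliest start on ties; drop arrays
    # contained in an accepted span
    candidates.sort(key=lambda sr: (-sr[0], sr[1].motif_length, sr[1].start))
    candidates = [r for _, r in candidates]
    accepted: list[TandemRepeat] = []
    for cand in candidates:
        c_end = cand.start + cand.copies * cand.motif_length + cand.spacer
        contained = False
        for acc in accepted:
            a_end = acc.start + acc.copies * acc.motif_length + acc.spacer
            if cand.start >= acc.start - acc.motif_length and c_end <= a_end + acc.motif_length:
                contained = True
                break
        if not contained:
            accepted.append(cand)
    accepted.sort(key=lambda r: (r.start, r.motif_length))
    return accepted


# ---------------------------------------------------------------------------
# per-genome convenience wrappers


def extract_cds(ann: MitoAnnotation, gene: str) -> str:
    """Strand-native coding sequence of one protein-coding gene."""
    f = ann.feature(gene)
    if f.ftype != "PCG":
        raise ValueError(f"{gene} is not a protein-coding gene")
    return f.extract(ann.seq, strand_native=True)


def classify_all_pcgs(ann: MitoAnnotation,
                      table_id: int = INVERTEBRATE_MITO_TABLE) -> list[CodonClassification]:
    return [classify_start_stop(extract_cds(ann, f.name), f.name, table_id)
            for f in ann.by_type("PCG")]


def genome_rscu(ann: MitoAnnotation,
                table_id: int = INVERTEBRATE_MITO_TABLE) -> CodonUsageTable:
    """RSCU over all PCGs of one genome, terminal stop codons trimmed."""
    cds_list = []
    for f in ann.by_type("PCG"):
        cds = extract_cds(ann, f.name)
        rem = len(cds) % 3
        if rem:
            cds = cds[:-rem]
        elif cds[-3:] in stop_codons(table_id):
            cds = cds[:-3]
        cds_list.append(cds)
    return rscu(cds_list, table_id)
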