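"""Seeded generators with known ground truth.

Two generators cover every downstream stage:

* :func:`simulate_barcodes` — multi-species COI barcode sets on a star
  phylogeny with a planted intraspecific/interspecific divergence gap
  and transition/transversion bias.  Substitution-only (no indels), so
  the sequences are born aligned.
* :func:`simulate_mitogenome` — circular annotated mitogenomes with the
  canonical 37-gene arthropod arrangement (23 genes on the majority J
  strand, 14 on the minority N strand), planted A+T content, AT-biased
  codon usage, start/stop codon assignments (including alternative GTG
  and incomplete T/TA stops), gene overlaps and intergenic spacers, and
  a tandem-repeat array in the AT-rich control region.

Both are pure functions of (config, seed) and return a truth table
recording every planted statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mitobarcode.mitocomp import (
    INVERTEBRATE_MITO_TABLE,
    stop_codons,
    synonymous_families,
    translate_codon,
)
from mitobarcode.seqio import (
    Alignment,
    GeneFeature,
    MitoAnnotation,
    SequenceRecord,
    reverse_complement,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_SPECIES_EPITHETS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
)


def _species_name(k: int) -> str:
    if k < len(_SPECIES_EPITHETS):
        return f"Simulitingis {_SPECIES_EPITHETS[k]}"
    return f"Simulitingis taxon{k + 1}"


# ---------------------------------------------------------------------------
# barcode simulation


@dataclass
class BarcodeSimConfig:
    """Study conditions for a synthetic barcode survey.

    Defaults emulate a small COI survey: 501-bp barcodes (the standard
    trimmed barcode alignment length), a star phylogeny of species
    ancestors each ``inter_div`` substitutions from the root (~8%
    divergence), shallow intraspecific variation (Poisson mean
    ``intra_lambda`` substitutions per individual), transition bias
    kappa and an AT-rich base composition typical of insect
    mitochondrial COI.
    """

    n_species: int = 4
    n_per_species: int = 12
    L: int = 501
    inter_div: int = 40
    intra_lambda: float = 2.0
    kappa: float = 4.0
    base_composition: tuple[float, float, float, float] = (0.31, 0.17, 0.15, 0.37)
    seed: int = 0


@dataclass
class BarcodeTruth:
    root: str
    ancestors: dict[str, str]
    mutations: dict[str, list[tuple[int, str, str]]]  # id -> (site, from, to)
    segregating_sites: dict[str, int]                 # realized S per species
    haplotype_partition: dict[str, dict[str, list[str]]]  # species -> hap -> ids
    config: BarcodeSimConfig


def _mutate(seq: list[str], site: int, rng: np.random.Generator,
            kappa: float) -> tuple[int, str, str]:
    old = seq[site]
    if rng.random() < kappa / (kappa + 2.0):
        new = _TRANSITION[old]
    else:
        new = _TRANSVERSIONS[old][rng.integers(0, 2)]
    seq[site] = new
    return site, old, new


def simulate_barcodes(cfg: BarcodeSimConfig) -> tuple[list[SequenceRecord], BarcodeTruth]:
    """Generate a labeled barcode dataset with recorded ground truth."""
    if abs(sum(cfg.base_composition) - 1.0) > 1e-9:
        raise ValueError("base_composition must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    root = "".join(rng.choice(list(_BASES), size=cfg.L,
                              p=list(cfg.base_composition)))
    ancestors: dict[str, str] = {}
    mutations: dict[str, list[tuple[int, str, str]]] = {}
    records: list[SequenceRecord] = []
    for k in range(cfg.n_species):
        sp = _species_name(k)
        anc = list(root)
        # distinct sites per ancestor: guarantees planted divergence
        sites = rng.choice(cfg.L, size=cfg.inter_div, replace=False)
        for site in sites:
            _mutate(anc, int(site), rng, cfg.kappa)
        ancestors[sp] = "".join(anc)
        for i in range(cfg.n_per_species):
            rec_id = f"SIM{k:02d}{i:03d}"
            indiv = list(anc)
            n_mut = rng.poisson(cfg.intra_lambda)
            muts = []
            if n_mut > 0:
                mut_sites = rng.choice(cfg.L, size=min(n_mut, cfg.L), replace=False)
                for site in mut_sites:
                    muts.append(_mutate(indiv, int(site), rng, cfg.kappa))
            mutations[rec_id] = muts
            records.append(SequenceRecord(id=rec_id, seq="".join(indiv),
                                          species=sp, source="simulated"))

    seg: dict[str, int] = {}
    partition: dict[str, dict[str, list[str]]] = {}
    for sp in ancestors:
        members = [r for r in records if r.species == sp]
        cols = 0
        for j in range(cfg.L):
            if len({r.seq[j] for r in members}) > 1:
                cols += 1
        seg[sp] = cols
        haps: dict[str, list[str]] = {}
        for r in members:
            haps.setdefault(r.seq, []).append(r.id)
        partition[sp] = haps
    truth = BarcodeTruth(root=root, ancestors=ancestors, mutations=mutations,
                         segregating_sites=seg, haplotype_partition=partition,
                         config=cfg)
    return records, truth


def simulate_outgroup(truth: BarcodeTruth, divergence: int = 100,
                      seed: int = 0, rec_id: str = "OUTG",
                      species: str = "Extaria group") -> SequenceRecord:
    """An outgroup sequence ``divergence`` substitutions from the root.

    Divergent enough to fall outside every ingroup cluster, mild enough
    that distance corrections stay defined.
    """
    rng = np.random.default_rng(seed)
    seq = list(truth.root)
    sites = rng.choice(len(seq), size=min(divergence, len(seq)), replace=False)
    for site in sites:
        _mutate(seq, int(site), rng, truth.config.kappa)
    return SequenceRecord(id=rec_id, seq="".join(seq), species=species,
                          source="simulated outgroup")


def barcode_alignment(records: list[SequenceRecord],
                      species: str | None = None) -> Alignment:
    """Alignment view of simulated records (optionally one species)."""
    subset = [r for r in records if species is None or r.species == species]
    return Alignment(subset)


# ---------------------------------------------------------------------------
# mitogenome simulation

#: canonical arthropod mitochondrial gene arrangement: (name, type,
#: strand, default length in bp).  23 features on J, 14 on N, control
#: region last (between 12S rRNA and the tRNA-Ile/Gln/Met cluster on
#: the circle).
CANONICAL_GENE_TABLE: tuple[tuple[str, str, str, int], ...] = (
    ("tRNA-Ile", "tRNA", "J", 66), ("tRNA-Gln", "tRNA", "N", 68),
    ("tRNA-Met", "tRNA", "J", 66), ("ND2", "PCG", "J", 1023),
    ("tRNA-Trp", "tRNA", "J", 66), ("tRNA-Cys", "tRNA", "N", 64),
    ("tRNA-Tyr", "tRNA", "N", 65), ("COI", "PCG", "J", 1536),
    ("tRNA-Leu2", "tRNA", "J", 66), ("COII", "PCG", "J", 684),
    ("tRNA-Lys", "tRNA", "J", 70), ("tRNA-Asp", "tRNA", "J", 66),
    ("ATP8", "PCG", "J", 159), ("ATP6", "PCG", "J", 678),
    ("COIII", "PCG", "J", 789), ("tRNA-Gly", "tRNA", "J", 65),
    ("ND3", "PCG", "J", 354), ("tRNA-Ala", "tRNA", "J", 63),
    ("tRNA-Arg", "tRNA", "J", 65), ("tRNA-Asn", "tRNA", "J", 66),
    ("tRNA-Ser1", "tRNA", "J", 67), ("tRNA-Glu", "tRNA", "J", 66),
    ("tRNA-Phe", "tRNA", "N", 66), ("ND5", "PCG", "N", 1719),
    ("tRNA-His", "tRNA", "N", 65), ("ND4", "PCG", "N", 1341),
    ("ND4L", "PCG", "N", 297), ("tRNA-Thr", "tRNA", "J", 66),
    ("tRNA-Pro", "tRNA", "N", 66), ("ND6", "PCG", "J", 525),
    ("CYTB", "PCG", "J", 1137), ("tRNA-Ser2", "tRNA", "J", 68),
    ("ND1", "PCG", "N", 936), ("tRNA-Leu1", "tRNA", "N", 66),
    ("16S-rRNA", "rRNA", "N", 1228), ("tRNA-Val", "tRNA", "N", 71),
    ("12S-rRNA", "rRNA", "N", 771), ("AT-rich", "control", "J", 780),
)

_DEFAULT_STARTS = {
    "ATP6": "ATG", "COIII": "ATG", "COI": "ATG", "CYTB": "ATG",
    "ND1": "ATG", "ND4": "ATG", "ND5": "ATG",
    "COII": "ATT", "ND2": "ATT", "ND6": "ATT",
    "ND4L": "ATA", "ND3": "GTG",  # the alternative-start case
}

#: complete TAA unless listed; "TA"/"T" are incomplete stops
_DEFAULT_STOPS = {
    "ND4": "TAG",
    "ND5": "T", "COII": "TA", "ND2": "TA",
}

#: (upstream, downstream, bp); the downstream partner of a PCG overlap
#: must be a filler feature so planted codons survive layout
_DEFAULT_OVERLAPS = (
    ("ND4L", "tRNA-Thr", 19),
    ("tRNA-Trp", "tRNA-Cys", 8),
    ("COIII", "tRNA-Gly", 1),
    ("tRNA-Ser1", "tRNA-Glu", 2),
)

_DEFAULT_SPACERS = (
    ("tRNA-Gln", "tRNA-Met", 10),
    ("tRNA-Ser2", "ND1", 9),
    ("tRNA-Glu", "tRNA-Phe", 6),
    ("ND6", "CYTB", 4),
    ("tRNA-Tyr", "COI", 3),
)


@dataclass
class RepeatPlant:
    motif_length: int = 170
    copies: int = 2
    spacer: int = 4


@dataclass
class MitoSimConfig:
    """Study conditions for one synthetic mitogenome.

    ``genome_length`` (when set) is hit exactly by resizing the AT-rich
    region; otherwise lengths follow the canonical gene table.  A+T
    targets: ``at_content`` drives filler/codon sampling genome-wide,
    ``control_at`` the AT-rich region.  Start/stop plants default to
    the arrangement typical of lace bug mitogenomes, including one
    alternative GTG start and incomplete T/TA stops.
    """

    genome_length: int | None = 15209
    at_content: float = 0.75
    control_at: float = 0.78
    starts: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_STARTS))
    stops: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_STOPS))
    overlaps: tuple[tuple[str, str, int], ...] = _DEFAULT_OVERLAPS
    spacers: tuple[tuple[str, str, int], ...] = _DEFAULT_SPACERS
    repeat: RepeatPlant | None = field(default_factory=RepeatPlant)
    organism: str = "Simulitingis synthetica"
    accession: str = "SYNTH01"
    table_id: int = INVERTEBRATE_MITO_TABLE
    seed: int = 0


@dataclass
class MitoTruth:
    genome_length: int
    strand_counts: tuple[int, int]               # (J, N) over the 37 genes
    starts: dict[str, str]
    stops: dict[str, str]
    overlaps: list[tuple[str, str, int]]
    spacers: list[tuple[str, str, int]]
    n_overlap_locations: int
    n_spacer_locations: int
    total_overlap_bp: int
    total_spacer_bp: int
    control_at_target: float
    control_length: int
    repeat: RepeatPlant | None
    repeat_start: int | None                     # within the control region
    at_rich_codons_favoured: tuple[str, ...]
    feature_table: list[tuple[str, str, str, int, int]]  # name,type,strand,start,end


def _codon_weights(at_content: float, table_id: int) -> tuple[list[str], np.ndarray]:
    """Sense codons weighted by an AT-biased base composition."""
    at_half = at_content / 2.0
    gc_half = (1.0 - at_content) / 2.0
    base_p = {"A": at_half * 1.05, "T": at_half * 0.95,
              "C": gc_half * 1.1, "G": gc_half * 0.9}
    stops = stop_codons(table_id)
    codons = sorted(c for fam in synonymous_families(table_id).values()
                    for c in fam if c not in stops)
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    return codons, w / w.sum()


def _sample_filler(rng: np.random.Generator, length: int, at: float) -> str:
    """Random sequence whose A+T content hits ``at`` to rounding.

    Exact base counts are shuffled rather than sampled, so planted
    composition targets are met deterministically even for short
    regions (sampling noise would otherwise be amplified when a region
    is duplicated into a repeat array).
    """
    n_a = round(length * at / 2)
    n_t = round(length * at) - n_a
    n_c = round(length * (1 - at) / 2)
    n_g = length - n_a - n_t - n_c
    bases = ["A"] * n_a + ["T"] * n_t + ["C"] * n_c + ["G"] * n_g
    return "".join(rng.permutation(bases))


def _build_cds(rng: np.random.Generator, length: int, start: str, stop: str,
               codons: list[str], weights: np.ndarray, table_id: int) -> str:
    """Planted-start/stop CDS with internal codons free of stops."""
    if stop in ("TA", "T"):
        body_len = length - 3 - len(stop)
        terminator = stop
    else:
        body_len = length - 6
        terminator = stop
    if body_len < 0 or body_len % 3:
        raise ValueError(
            f"CDS length {length} incompatible with stop {stop!r}")
    n_codons = body_len // 3
    body = "".join(rng.choice(codons, size=n_codons, p=weights))
    return start + body + terminator


def simulate_mitogenome(cfg: MitoSimConfig) -> tuple[MitoAnnotation, MitoTruth]:
    """Generate an annotated circular mitogenome and its truth table."""
    rng = np.random.default_rng(cfg.seed)
    overlaps = {(u, d): bp for u, d, bp in cfg.overlaps}
    spacers = {(u, d): bp for u, d, bp in cfg.spacers}
    table = [list(row) for row in CANONICAL_GENE_TABLE]

    # adjust PCG lengths for incomplete stop plants (mod-3 convention)
    for row in table:
        name, ftype, _, length = row
        if ftype == "PCG":
            stop = cfg.stops.get(name, "TAA")
            if stop == "TA":
                row[3] = length - 1
            elif stop == "T":
                row[3] = length - 2
            elif stop not in ("TAA", "TAG"):
                raise ValueError(f"{name}: unknown stop plant {stop!r}")

    # resize the control region to hit the genome-length target
    names = [row[0] for row in table]
    adjacency = list(zip(names, names[1:] + names[:1]))
    by_name = {r[0]: r for r in table}
    for (u, d), bp in overlaps.items():
        if (u, d) not in adjacency:
            raise ValueError(f"overlap plant {u}->{d}: features not adjacent")
        if min(by_name[u][3], by_name[d][3]) <= bp:
            raise ValueError(f"overlap plant {u}->{d}: longer than the gene")
        if by_name[u][1] == "PCG" and by_name[d][1] == "PCG":
            raise ValueError(
                f"overlap plant {u}->{d}: PCG-PCG overlaps would corrupt "
                "planted codons; one partner must be a filler feature")
    for (u, d) in spacers:
        if (u, d) not in adjacency:
            raise ValueError(f"spacer plant {u}->{d}: features not adjacent")
    layout_delta = sum(spacers.values()) - sum(overlaps.values())
    non_control = sum(row[3] for row in table if row[1] != "control")
    if cfg.genome_length is not None:
        control_len = cfg.genome_length - non_control - layout_delta
    else:
        control_len = next(row[3] for row in table if row[1] == "control")
    min_control = 50
    if cfg.repeat is not None:
        min_control = (cfg.repeat.motif_length * cfg.repeat.copies
                       + cfg.repeat.spacer * (cfg.repeat.copies - 1) + 20)
    if control_len < min_control:
        raise ValueError(f"control region too short ({control_len} bp) for plants")
    for row in table:
        if row[1] == "control":
            row[3] = control_len

    # lay out coordinates (linear; control region ends the circle)
    features: list[GeneFeature] = []
    pos = 0
    prev_name = None
    for name, ftype, strand, length in table:
        if prev_name is not None:
            pos -= overlaps.get((prev_name, name), 0)
            pos += spacers.get((prev_name, name), 0)
        features.append(GeneFeature(name=name, ftype=ftype,
                                    start=pos, end=pos + length, strand=strand))
        pos = pos + length
        prev_name = name
    genome_length = pos

    # fill sequence: filler features first, then PCGs (PCG plants win
    # inside overlap regions), then the control region with its repeat
    seq = list(_sample_filler(rng, genome_length, cfg.at_content))
    codons, weights = _codon_weights(cfg.at_content, cfg.table_id)
    for f in features:
        if f.ftype != "PCG":
            continue
        start = cfg.starts.get(f.name, "ATG")
        stop = cfg.stops.get(f.name, "TAA")
        cds = _build_cds(rng, f.end - f.start, start, stop, codons, weights,
                         cfg.table_id)
        placed = reverse_complement(cds) if f.strand == "N" else cds
        seq[f.start: f.end] = list(placed)

    control = next(f for f in features if f.ftype == "control")
    repeat_start = None
    if cfg.repeat is None:
        control_seq = list(_sample_filler(rng, control_len, cfg.control_at))
    else:
        r = cfg.repeat
        motif = _sample_filler(rng, r.motif_length, cfg.control_at)
        array = motif
        for _ in range(r.copies - 1):
            array += _sample_filler(rng, r.spacer, cfg.control_at) + motif
        repeat_start = control_len - len(array)
        # prefix sampled at exact counts on its own length, so the
        # planted A+T target holds for the whole region, not just in
        # expectation
        control_seq = list(_sample_filler(rng, repeat_start, cfg.control_at)
                           + array)
        # phase guard: the bases just upstream of the array must differ
        # from their images one period downstream, otherwise a window
        # slid off the planted phase describes the same array equally
        # well and the recovered motif length becomes ambiguous
        period = r.motif_length + r.spacer
        for i in range(1, min(9, repeat_start + 1)):
            image = control_seq[repeat_start + period - i]
            if control_seq[repeat_start - i] == image:
                pool = [b for b in "AT" if b != image] or ["C"]
                control_seq[repeat_start - i] = pool[int(rng.integers(0, len(pool)))]
    seq[control.start: control.end] = control_seq

    ann = MitoAnnotation(seq="".join(seq), features=features,
                         accession=cfg.accession, organism=cfg.organism)

    genes = [f for f in features if f.ftype != "control"]
    j_count = sum(1 for f in genes if f.strand == "J")
    truth = MitoTruth(
        genome_length=genome_length,
        strand_counts=(j_count, len(genes) - j_count),
        starts={f.name: cfg.starts.get(f.name, "ATG")
                for f in features if f.ftype == "PCG"},
        stops={f.name: cfg.stops.get(f.name, "TAA")
               for f in features if f.ftype == "PCG"},
        overlaps=[(u, d, bp) for (u, d), bp in overlaps.items()],
        spacers=[(u, d, bp) for (u, d), bp in spacers.items()],
        n_overlap_locations=len(overlaps),
        n_spacer_locations=len(spacers),
        total_overlap_bp=sum(overlaps.values()),
        total_spacer_bp=sum(spacers.values()),
        control_at_target=cfg.control_at,
        control_length=control_len,
        repeat=cfg.repeat,
        repeat_start=repeat_start,
        at_rich_codons_favoured=("TTT", "TTA", "ATT", "ATA", "TAT", "AAT", "AAA"),
        feature_table=[(f.name, f.ftype, f.strand, f.start, f.end)
                       for f in features],
    )
    return ann, truth


def mutate_mitogenome(
    ann: MitoAnnotation,
    syn_prob: float = 0.05,
    nonsyn_prob: float = 0.01,
    filler_prob: float = 0.02,
    seed: int = 0,
    accession: str = "SYNTH02",
    organism: str = "Simulitingis mutata",
    table_id: int = INVERTEBRATE_MITO_TABLE,
) -> MitoAnnotation:
    """Derive a related genome with a planted purifying regime.

    Each internal PCG codon receives, independently, a synonymous
    single-nucleotide change with probability ``syn_prob`` and a
    nonsynonymous one with probability ``nonsyn_prob`` (stop-creating
    changes never applied); with the defaults the planted Ka/Ks is
    well below 1.  Filler features and intergenic sequence mutate at
    ``filler_prob`` per site.  Coordinates and feature table are
    preserved, so the derived genome aligns to its parent gene-by-gene
    without alignment.
    """
    rng = np.random.default_rng(seed)
    stops = stop_codons(table_id)
    seq = list(ann.seq)

    pcg_positions: set[int] = set()
    for f in ann.features:
        if f.ftype != "PCG":
            continue
        cds = list(f.extract(ann.seq, strand_native=True))
        n_codons = len(cds) // 3
        for ci in range(1, n_codons - 1):  # keep start and terminator
            codon = "".join(cds[3 * ci: 3 * ci + 3])
            if codon in stops or set(codon) - set(_BASES):
                continue
            aa = translate_codon(codon, table_id)
            want_syn = rng.random() < syn_prob
            want_non = rng.random() < nonsyn_prob
            if not (want_syn or want_non):
                continue
            neighbours = []
            for pos in range(3):
                for b in _BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1:]
                    if mut in stops:
                        continue
                    is_syn = translate_codon(mut, table_id) == aa
                    if (want_syn and is_syn) or (want_non and not is_syn):
                        neighbours.append(mut)
            if neighbours:
                pick = neighbours[int(rng.integers(0, len(neighbours)))]
                cds[3 * ci: 3 * ci + 3] = list(pick)
        mutated = "".join(cds)
        placed = reverse_complement(mutated) if f.strand == "N" else mutated
        lo = f.start
        for i, b in enumerate(placed):
            seq[lo + i] = b
        for i in range(f.start, f.end):
            pcg_positions.add(i)

    for i in range(len(seq)):
        if i in pcg_positions:
            continue
        if rng.random() < filler_prob:
            _mutate(seq, i, rng, 2.0)

    return MitoAnnotation(seq="".join(seq), features=[
        GeneFeature(f.name, f.ftype, f.start, f.end, f.strand)
        for f in ann.features], accession=accession, organism=organism)
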