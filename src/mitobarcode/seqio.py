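"""Sequence and annotation I/O.

Reads and writes the formats the pipeline touches (FASTA, GenBank
flatfile, tab-separated id-to-species maps) and normalizes everything
into the internal types.  Internally all coordinates are 0-based
half-open; the 1-based inclusive convention of GenBank/FASTA exists only
at the file boundary.  Features that span the circular origin are stored
with ``end < start`` and materialized as ``seq[start:] + seq[:end]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as _BioRecord

ALPHABET = frozenset("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Canonical arthropod mitochondrial gene names by feature class.
PCG_NAMES = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)
RRNA_NAMES = ("16S-rRNA", "12S-rRNA")
CONTROL_NAME = "AT-rich"


def normalize_seq(raw: str) -> str:
    """Uppercase, map U to T, and validate against the DNA alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)!r}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A labeled DNA sequence (one barcode read, one genome, ...)."""

    id: str
    seq: str
    species: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")

    @property
    def ungapped_length(self) -> int:
        return len(self.seq) - self.seq.count("-")


@dataclass
class Alignment:
    """Equal-length sequence records; ``length`` is the column count."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            offenders = sorted({r.id for r in self.records})
            raise ValueError(f"unequal sequence lengths in alignment: {offenders}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class GeneFeature:
    """A gene on a circular mitogenome.

    ``start``/``end`` are 0-based half-open on the published (J-strand)
    representation; ``end < start`` marks a feature wrapping the circular
    origin.  ``strand`` is "J" (majority, GenBank "+") or "N" (minority,
    GenBank "-").
    """

    name: str
    ftype: str  # PCG | tRNA | rRNA | control
    start: int
    end: int
    strand: str = "J"

    def __post_init__(self) -> None:
        if self.ftype not in ("PCG", "tRNA", "rRNA", "control"):
            raise ValueError(f"{self.name}: unknown feature type {self.ftype!r}")
        if self.strand not in ("J", "N"):
            raise ValueError(f"{self.name}: strand must be J or N")
        if self.start < 0 or self.end < 0:
            raise ValueError(f"{self.name}: negative coordinate")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + self.end
        return self.end - self.start

    def extract(self, genome: str, *, strand_native: bool = True) -> str:
        """Feature sequence; reverse-complemented for N-strand features
        unless ``strand_native`` is False."""
        if self.wraps:
            sub = genome[self.start:] + genome[: self.end]
        else:
            sub = genome[self.start: self.end]
        if strand_native and self.strand == "N":
            sub = reverse_complement(sub)
        return sub


@dataclass
class MitoAnnotation:
    """Circular genome sequence plus its ordered gene features."""

    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    accession: str = ""
    organism: str = ""

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        self.features.sort(key=lambda f: (f.start, f.end))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def genome_length(self) -> int:
        return len(self.seq)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]


# ---------------------------------------------------------------------------
# coordinate conversion


def to_internal(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str, species_map: dict[str, str] | None) -> tuple[str, str]:
    tokens = header.split()
    rec_id = tokens[0]
    if species_map is not None:
        return rec_id, species_map.get(rec_id, "")
    # default dialect: species = tokens after the accession, joined
    return rec_id, " ".join(tokens[1:])


def read_fasta(path: str | Path, species_map: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into records.

    The species label is the header remainder after the id token, or the
    value of ``species_map`` (id -> species) when supplied.  Empty
    headers, duplicate ids and illegal characters raise ``ValueError``
    naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        header = bio.description.strip()
        if not header:
            raise ValueError(f"{path}: empty FASTA header")
        rec_id, species = _parse_header(header, species_map)
        if rec_id in seen:
            raise ValueError(f"{path}: duplicate record id {rec_id!r}")
        seen.add(rec_id)
        try:
            rec = SequenceRecord(id=rec_id, seq=str(bio.seq), species=species,
                                 source=str(path))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec_id!r}: {exc}") from exc
        records.append(rec)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records as FASTA, header = ``id species`` when species set."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f"{rec.id} {rec.species}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i: i + width] + "\n")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column tab-separated id -> species mapping file."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        mapping[parts[0]] = parts[1]
    return mapping


def read_alignment(path: str | Path, species_map: dict[str, str] | None = None) -> Alignment:
    """Read an aligned FASTA; unequal lengths are rejected listing ids."""
    records = read_fasta(path, species_map)
    if not records:
        raise ValueError(f"{path}: empty alignment file")
    return Alignment(records)


# ---------------------------------------------------------------------------
# GenBank flatfile

_FEATURE_TYPE_MAP = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control",
}

_CONTROL_HINTS = re.compile(r"AT[- ]rich|control region|D-loop", re.IGNORECASE)


def _canonical_name(bio_feature) -> str:
    for key in ("gene", "product", "note"):
        if key in bio_feature.qualifiers:
            return str(bio_feature.qualifiers[key][0])
    return bio_feature.type


def read_genbank(path: str | Path) -> MitoAnnotation:
    """Parse a GenBank flatfile into a :class:`MitoAnnotation`.

    gene/CDS/tRNA/rRNA/D-loop/misc_feature entries become features;
    strand comes from ``complement(...)``; coordinates convert to the
    internal 0-based half-open convention.  An origin-spanning join is
    stored with ``end < start``.
    """
    path = Path(path)
    try:
        bio = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse GenBank flatfile: {exc}") from exc
    seq = str(bio.seq)
    if not seq or set(seq) == {"N"}:
        raise ValueError(f"{path}: missing or empty ORIGIN sequence")

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for bf in bio.features:
        if bf.type == "gene" or bf.type == "source":
            continue  # gene entries duplicate CDS/tRNA/rRNA spans
        name = _canonical_name(bf)
        if bf.type == "misc_feature":
            if not _CONTROL_HINTS.search(name):
                continue
            ftype = "control"
            name = CONTROL_NAME
        elif bf.type in _FEATURE_TYPE_MAP:
            ftype = _FEATURE_TYPE_MAP[bf.type]
            if ftype == "control":
                name = CONTROL_NAME
        else:
            continue
        if name in seen:
            continue
        seen.add(name)
        loc = bf.location
        if loc is None:
            raise ValueError(f"{path}: feature {name!r}: unparseable location")
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) == 1:
            start, end = int(parts[0].start), int(parts[0].end)
        elif len(parts) == 2 and int(parts[1].end) == len(seq) and int(parts[0].start) == 0:
            # join(x..N, 1..y): wraps the circular origin
            start, end = int(parts[1].start), int(parts[0].end)
        else:
            raise ValueError(f"{path}: feature {name!r}: unsupported compound location")
        strand = "N" if loc.strand == -1 else "J"
        features.append(GeneFeature(name=name, ftype=ftype, start=start, end=end,
                                    strand=strand))
    return MitoAnnotation(seq=seq, features=features, accession=bio.id,
                          organism=bio.annotations.get("organism", ""))


def write_genbank(ann: MitoAnnotation, path: str | Path) -> None:
    """Serialize an annotation back to a GenBank flatfile."""
    bio = _BioRecord(Seq(ann.seq), id=ann.accession or "SYNTH01",
                     name=(ann.accession or "SYNTH01")[:16],
                     description=f"{ann.organism} mitochondrion, complete genome".strip(),
                     annotations={"molecule_type": "DNA", "topology": "circular",
                                  "organism": ann.organism or "synthetic organism"})
    for f in ann.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps:
            from Bio.SeqFeature import CompoundLocation
            loc = CompoundLocation([
                FeatureLocation(f.start, len(ann.seq), strand=strand),
                FeatureLocation(0, f.end, strand=strand),
            ])
        else:
            loc = FeatureLocation(f.start, f.end, strand=strand)
        if f.ftype == "PCG":
            btype, quals = "CDS", {"gene": [f.name]}
        elif f.ftype == "control":
            btype, quals = "misc_feature", {"note": ["AT-rich region (control region)"]}
        else:
            btype, quals = f.ftype, {"gene": [f.name], "product": [f.name]}
        bio.features.append(SeqFeature(loc, type=btype, qualifiers=quals))
    with Path(path).open("w") as fh:
        SeqIO.write(bio, fh, "genbank")
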