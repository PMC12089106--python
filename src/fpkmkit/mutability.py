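"""Cross-species mutability scoring of gene loci.

Two binary per-gene factors: F(i), proximity of the locus to the nearest
chromosome end (< 50 Mb, strict), and F(ii), high A+T content of the gene
span (> 0.59, strict).  Per-species matching rates summarize how often a
gene panel satisfies each factor.  Auxiliary rules: linkage classification
at the 50 cM cutoff (inclusive) and the 1 cM ~ 1 Mb scaling.  Transcript
sizes across species are flagged against a reference panel range.

Coordinates are 1-based inclusive at the interface (GFF3 convention); BED
input is converted from 0-based half-open on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import ArgumentError, ParseError, ValidationError

F_I_THRESHOLD_MB = 50.0
F_II_THRESHOLD = 0.59


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeInfo:
    species: str
    chromosome_name: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(
                f"chromosome {self.species}/{self.chromosome_name}: "
                f"non-positive length {self.length_bp}"
            )


@dataclass(frozen=True)
class GeneLocus:
    """1-based inclusive span of a gene on a chromosome."""

    species: str
    gene_id: str
    chromosome_name: str
    start_bp: int
    end_bp: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValidationError(
                f"locus {self.gene_id}: invalid span [{self.start_bp}, {self.end_bp}]"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"locus {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class FactorCall:
    gene_id: str
    species: str
    telomere_distance_mb: float
    f_i: bool
    at_fraction: float
    f_ii: bool


@dataclass(frozen=True)
class MatchingRateSummary:
    species: str
    factor: str  # "f_i" or "f_ii"
    n_genes: int
    n_matching: int

    @property
    def rate_fraction(self) -> float:
        return self.n_matching / self.n_genes

    @property
    def rate_percent(self) -> int:
        """Nearest-integer percentage, the form used in reporting."""
        return round(100.0 * self.n_matching / self.n_genes)


@dataclass(frozen=True)
class TranscriptRecord:
    species: str
    gene_id: str
    transcript_length_bp: int

    def __post_init__(self) -> None:
        if self.transcript_length_bp <= 0:
            raise ValidationError(
                f"transcript {self.species}/{self.gene_id}: non-positive length"
            )


@dataclass(frozen=True)
class ReferenceSizeRange:
    panel_name: str
    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.max_bp:
            raise ValidationError(
                f"reference range {self.panel_name!r}: "
                f"invalid [{self.min_bp}, {self.max_bp}]"
            )


@dataclass(frozen=True)
class SizeConservationResult:
    gene_id: str
    flags: dict[str, str]  # species -> "typical" | "unusual"
    length_ratio: float  # max/min transcript length across species


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def telomere_distance(locus: GeneLocus, chrom: ChromosomeInfo) -> float:
    """Distance in Mb from the locus to the nearest chromosome end.

    ``min(start - 1, length - end) / 1e6``; a gene touching either end is
    at distance 0.
    """
    if (locus.species, locus.chromosome_name) != (chrom.species, chrom.chromosome_name):
        raise ValidationError(
            f"locus {locus.gene_id} on {locus.species}/{locus.chromosome_name} does "
            f"not match chromosome {chrom.species}/{chrom.chromosome_name}"
        )
    if locus.end_bp > chrom.length_bp:
        raise ValidationError(
            f"locus {locus.gene_id} end {locus.end_bp} exceeds chromosome "
            f"length {chrom.length_bp}"
        )
    return min(locus.start_bp - 1, chrom.length_bp - locus.end_bp) / 1e6


def classify_f_i(distance_mb: float, threshold_mb: float = F_I_THRESHOLD_MB) -> bool:
    """Telomere-proximal iff distance < threshold (strict); 50 Mb is not."""
    if distance_mb < 0:
        raise ArgumentError(f"negative telomere distance: {distance_mb}")
    return distance_mb < threshold_mb


def at_content(sequence: str) -> float:
    """(A + T) / unambiguous bases, case-insensitive; N etc. excluded."""
    if not sequence:
        raise ArgumentError("empty sequence")
    seq = sequence.upper()
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    unambiguous = at + gc
    if unambiguous == 0:
        raise ArgumentError("sequence contains no unambiguous A/C/G/T bases")
    return at / unambiguous


def classify_f_ii(at_fraction: float, threshold: float = F_II_THRESHOLD) -> bool:
    """High A+T iff fraction > threshold (strict); exactly 0.59 is not."""
    if not 0.0 <= at_fraction <= 1.0:
        raise ArgumentError(f"A+T fraction outside [0, 1]: {at_fraction}")
    return at_fraction > threshold


def linkage_status(recombination_cm: float) -> Literal["linked", "unlinked"]:
    """Linked iff recombination frequency <= 50 cM (inclusive)."""
    if recombination_cm < 0:
        raise ArgumentError(f"negative recombination frequency: {recombination_cm}")
    return "linked" if recombination_cm <= 50.0 else "unlinked"


def cm_to_mb(genetic_distance_cm: float) -> float:
    """1 cM approximately equals 1 Mb (identity scaling)."""
    if genetic_distance_cm < 0:
        raise ArgumentError(f"negative genetic distance: {genetic_distance_cm}")
    return float(genetic_distance_cm)


def matching_rate(
    calls: Sequence[FactorCall], species: str, factor: Literal["f_i", "f_ii"]
) -> MatchingRateSummary:
    """Fraction of a species' panel whose factor flag is true."""
    if factor not in ("f_i", "f_ii"):
        raise ArgumentError(f"unknown factor {factor!r}")
    sub = [c for c in calls if c.species == species]
    if not sub:
        raise ArgumentError(f"no factor calls for species {species!r}")
    n_match = sum(1 for c in sub if getattr(c, factor))
    return MatchingRateSummary(
        species=species, factor=factor, n_genes=len(sub), n_matching=n_match
    )


def size_conservation(
    records: Sequence[TranscriptRecord], reference: ReferenceSizeRange
) -> SizeConservationResult:
    """Flag per-species transcript lengths against a reference panel range.

    A species is "unusual" when its transcript falls outside the
    reference's [min_bp, max_bp]; the max/min length ratio across species
    is reported as a conservation score (1 = perfectly conserved size).
    """
    if len(records) < 2:
        raise ArgumentError("size conservation needs records for >= 2 species")
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ArgumentError(f"records span multiple genes: {sorted(genes)}")
    species = [r.species for r in records]
    if len(set(species)) != len(species):
        raise ArgumentError("duplicate species in transcript records")
    lengths = [r.transcript_length_bp for r in records]
    flags = {
        r.species: (
            "typical"
            if reference.min_bp <= r.transcript_length_bp <= reference.max_bp
            else "unusual"
        )
        for r in records
    }
    return SizeConservationResult(
        gene_id=next(iter(genes)),
        flags=flags,
        length_ratio=max(lengths) / min(lengths),
    )


# ---------------------------------------------------------------------------
# Batch scoring
# ---------------------------------------------------------------------------

def factor_calls(
    loci: Sequence[GeneLocus],
    chromosomes: Mapping[tuple[str, str], ChromosomeInfo],
    sequences: Mapping[str, str] | "object",
    threshold_i_mb: float = F_I_THRESHOLD_MB,
    threshold_ii: float = F_II_THRESHOLD,
) -> list[FactorCall]:
    """Compute both factors for every locus.

    ``sequences`` maps chromosome name to sequence — a plain dict or any
    object with ``__getitem__`` returning a sliceable sequence (e.g. a
    :class:`pyfaidx.Fasta`).  A+T content is computed over the genomic gene
    span ``[start, end]``.
    """
    calls: list[FactorCall] = []
    for locus in loci:
        key = (locus.species, locus.chromosome_name)
        if key not in chromosomes:
            raise ValidationError(f"no chromosome record for {key}")
        dist = telomere_distance(locus, chromosomes[key])
        seq = sequences[locus.chromosome_name][locus.start_bp - 1 : locus.end_bp]
        at = at_content(str(seq))
        calls.append(
            FactorCall(
                gene_id=locus.gene_id,
                species=locus.species,
                telomere_distance_mb=dist,
                f_i=classify_f_i(dist, threshold_i_mb),
                at_fraction=at,
                f_ii=classify_f_ii(at, threshold_ii),
            )
        )
    return calls


def calls_table(calls: Sequence[FactorCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "species": c.species,
                "telomere_distance_mb": c.telomere_distance_mb,
                "f_i": c.f_i,
                "at_fraction": c.at_fraction,
                "f_ii": c.f_ii,
            }
            for c in calls
        ]
    )


def matching_rate_table(calls: Sequence[FactorCall]) -> pd.DataFrame:
    rows = []
    for species in sorted({c.species for c in calls}):
        for factor in ("f_i", "f_ii"):
            s = matching_rate(calls, species, factor)
            rows.append(
                {
                    "species": s.species,
                    "factor": s.factor,
                    "n_genes": s.n_genes,
                    "n_matching": s.n_matching,
                    "rate_percent": s.rate_percent,
                    "rate_fraction": s.rate_fraction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_chromosome_lengths(path: str | Path, species: str) -> dict[tuple[str, str], ChromosomeInfo]:
    """Two-column TSV: chromosome name, length in bp."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=None, names=["name", "length_bp"])
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty chromosome-length table: {path}") from exc
    out: dict[tuple[str, str], ChromosomeInfo] = {}
    for _, row in frame.iterrows():
        key = (species, str(row["name"]))
        if key in out:
            raise ValidationError(f"duplicate chromosome record {key}")
        out[key] = ChromosomeInfo(
            species=species, chromosome_name=str(row["name"]), length_bp=int(row["length_bp"])
        )
    return out


def read_loci_gff3(path: str | Path, species: str, feature_type: str = "gene") -> list[GeneLocus]:
    """Extract gene loci from a GFF3 file (1-based inclusive, as written)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    loci: list[GeneLocus] = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = (
            feat.attributes.get("gene_id", [None])[0]
            or feat.attributes.get("Name", [None])[0]
            or feat.id
        )
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        loci.append(
            GeneLocus(
                species=species,
                gene_id=gene_id,
                chromosome_name=feat.seqid,
                start_bp=feat.start,
                end_bp=feat.end,
                strand=strand,
            )
        )
    if not loci:
        raise ParseError(f"no {feature_type!r} features in {path}")
    return loci


def read_loci_bed(path: str | Path, species: str) -> list[GeneLocus]:
    """6-column BED, 0-based half-open; converted to 1-based inclusive."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
    except (pd.errors.EmptyDataError, ValueError) as exc:
        raise ParseError(f"bad BED file {path}: {exc}") from exc
    loci = []
    for _, row in frame.iterrows():
        strand = row["strand"] if row["strand"] in ("+", "-") else "unknown"
        loci.append(
            GeneLocus(
                species=species,
                gene_id=str(row["name"]),
                chromosome_name=str(row["chrom"]),
                start_bp=int(row["start"]) + 1,
                end_bp=int(row["end"]),
                strand=strand,
            )
        )
    if not loci:
        raise ParseError(f"no intervals in {path}")
    return loci


def read_transcript_lengths(path: str | Path) -> list[TranscriptRecord]:
    """TSV with header: species, gene_id, transcript_length_bp."""
    frame = pd.read_csv(path, sep="\t")
    required = {"species", "gene_id", "transcript_length_bp"}
    if not required.issubset(frame.columns):
        raise ParseError(f"transcript table needs columns {sorted(required)}")
    return [
        TranscriptRecord(
            species=str(r["species"]),
            gene_id=str(r["gene_id"]),
            transcript_length_bp=int(r["transcript_length_bp"]),
        )
        for _, r in frame.iterrows()
    ]


def open_fasta(path: str | Path):
    """Open an (optionally indexed) FASTA for region extraction."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def check_fasta_lengths(
    chromosomes: Mapping[tuple[str, str], ChromosomeInfo], fasta
) -> None:
    """When both a length table and sequence are given, they must agree.

    The table remains authoritative; any mismatch with the FASTA is an
    error rather than a silent override.
    """
    for (species, name), info in chromosomes.items():
        if name in fasta:
            actual = len(fasta[name])
            if actual != info.length_bp:
                raise ValidationError(
                    f"chromosome {species}/{name}: length table says "
                    f"{info.length_bp} bp but FASTA has {actual} bp"
                )
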