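"""Seeded generators for every input the pipeline consumes.

Expression matrices come from a log-normal model: per-gene baseline log2
means, additive per-batch and per-sample-cell noise in log space, spiked
group effects of known fold change, and an optional control sample drawn
with the disease-group effects applied (a designed outlier).  Genomes are
random sequences with gene spans placed at exact telomere distances and
sampled to a target A+T fraction.  Gene-set collections embed one set whose
members carry a designed expression spike.

Every generator is a pure function of its spec plus seed; truth records
describe each designed effect so downstream recovery tests never need the
generator's internals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet
from .errors import ArgumentError
from .expression import ExpressionMatrix, SampleTable
from .mutability import ChromosomeInfo, GeneLocus

DEFAULT_GROUP_SIZES = {"control": 5, "AD": 6, "PD": 3}


@dataclass(frozen=True)
class TruthRecord:
    entity: str
    prop: str
    value: object

    def to_dict(self) -> dict:
        return {"entity": self.entity, "property": self.prop, "value": self.value}


@dataclass(frozen=True)
class Spike:
    """A designed group effect: the group's log2 mean is shifted by
    +/- log2(fold) for the given gene."""

    gene_index: int
    group: str  # "AD" or "PD" (or "control")
    fold: float
    direction: str  # "up" or "down"

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ArgumentError(f"spike fold must be >= 1, got {self.fold}")
        if self.direction not in ("up", "down"):
            raise ArgumentError(f"spike direction must be up/down, got {self.direction}")


@dataclass
class ExpressionSimSpec:
    n_genes: int = 1000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 2.0
    spike_table: list[Spike] = field(default_factory=list)
    batch_effect_sd: float = 0.0
    noise_log_sd: float = 0.5
    outlier_control_index: int | None = None
    seed: int = 0


def _subseed(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-stream generator derived from one global seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_fpkm(
    spec: ExpressionSimSpec,
) -> tuple[ExpressionMatrix, SampleTable, list[TruthRecord]]:
    """Simulate an FPKM matrix with known group effects.

    Per-gene baseline log2 means are normal; each cell is
    ``2 ** (mu_g + spike + batch + noise)``.  Spiked genes shift the target
    group's log2 mean by ``±log2(fold)``.  ``outlier_control_index`` picks
    one control sample that additionally receives every AD spike, emulating
    a control specimen that clusters with the disease samples.
    """
    for g, n in spec.group_sizes.items():
        if n < 1:
            raise ArgumentError(f"group {g!r} needs >= 1 sample")
    for sp in spec.spike_table:
        if not 0 <= sp.gene_index < spec.n_genes:
            raise ArgumentError(f"spike gene index {sp.gene_index} out of range")
        if sp.group not in spec.group_sizes:
            raise ArgumentError(f"spike group {sp.group!r} not simulated")
    n_ctrl = spec.group_sizes.get("control", 0)
    if spec.outlier_control_index is not None and not (
        0 <= spec.outlier_control_index < n_ctrl
    ):
        raise ArgumentError("outlier_control_index out of range")

    rng = _subseed(spec.seed, 0)
    width = len(str(spec.n_genes))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(spec.n_genes)]

    sample_ids: list[str] = []
    groups: list[str] = []
    batches: list[str] = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        for j in range(n):
            sample_ids.append(f"{group}_{j + 1}")
            groups.append(group)
            # split each group across the two acquisition sessions
            batches.append("session1" if j < (n + 1) // 2 else "session2")

    mu = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=spec.n_genes)
    batch_shift = {
        "session1": rng.normal(0.0, spec.batch_effect_sd) if spec.batch_effect_sd else 0.0,
        "session2": rng.normal(0.0, spec.batch_effect_sd) if spec.batch_effect_sd else 0.0,
    }
    spike_shift = np.zeros((spec.n_genes, len(sample_ids)))
    outlier_sample = (
        f"control_{spec.outlier_control_index + 1}"
        if spec.outlier_control_index is not None
        else None
    )
    for sp in spec.spike_table:
        delta = np.log2(sp.fold) * (1 if sp.direction == "up" else -1)
        for sj, (sid, grp) in enumerate(zip(sample_ids, groups)):
            if grp == sp.group or (sp.group == "AD" and sid == outlier_sample):
                spike_shift[sp.gene_index, sj] += delta

    noise = rng.normal(0.0, spec.noise_log_sd, size=(spec.n_genes, len(sample_ids)))
    log_values = (
        mu[:, None]
        + spike_shift
        + np.array([batch_shift[b] for b in batches])[None, :]
        + noise
    )
    values = np.power(2.0, log_values)
    matrix = ExpressionMatrix(values, gene_ids, sample_ids)
    meta = SampleTable(
        pd.DataFrame({"sample_id": sample_ids, "group": groups, "batch": batches})
    )

    truths = [
        TruthRecord(
            entity=gene_ids[sp.gene_index],
            prop=f"true_fold_{sp.group}",
            value=sp.fold if sp.direction == "up" else 1.0 / sp.fold,
        )
        for sp in spec.spike_table
    ]
    if outlier_sample is not None:
        truths.append(TruthRecord(entity=outlier_sample, prop="outlier_control", value=True))
    return matrix, meta, truths


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    chromosome: str
    target_telomere_distance_mb: float
    length_bp: int
    target_at_fraction: float


@dataclass
class GenomeSimSpec:
    chromosomes: list[tuple[str, int]]
    gene_placements: list[GenePlacement]
    background_at_fraction: float = 0.5
    seed: int = 0


def simulate_genome(
    spec: GenomeSimSpec,
) -> tuple[dict[str, str], list[GeneLocus], list[ChromosomeInfo], list[TruthRecord]]:
    """Random chromosome sequences with genes at designed positions.

    Each gene starts at ``target_distance + 1`` bp from the left end, which
    must be the nearer end, so ``telomere_distance`` recovers the target
    exactly.  Gene-span bases are A/T with the target probability; the
    background uses ``background_at_fraction``.
    """
    chrom_len = dict(spec.chromosomes)
    for p in spec.gene_placements:
        if p.chromosome not in chrom_len:
            raise ArgumentError(f"placement {p.gene_id}: unknown chromosome {p.chromosome}")
        if not 0.0 < p.target_at_fraction <= 1.0:
            raise ArgumentError(f"placement {p.gene_id}: A+T target must be in (0, 1]")
        start = int(round(p.target_telomere_distance_mb * 1e6)) + 1
        end = start + p.length_bp - 1
        length = chrom_len[p.chromosome]
        if end > length:
            raise ArgumentError(
                f"placement {p.gene_id} does not fit on {p.chromosome} ({length} bp)"
            )
        if length - end < start - 1:
            raise ArgumentError(
                f"placement {p.gene_id}: right end is nearer than the target "
                f"distance; enlarge the chromosome"
            )

    rng = _subseed(spec.seed, 1)
    bases = np.frombuffer(b"ATGC", dtype="S1")
    bg = spec.background_at_fraction
    probs = np.array([bg / 2, bg / 2, (1 - bg) / 2, (1 - bg) / 2])
    seqs: dict[str, np.ndarray] = {
        name: rng.choice(bases, size=length, p=probs)
        for name, length in spec.chromosomes
    }
    loci: list[GeneLocus] = []
    truths: list[TruthRecord] = []
    for p in spec.gene_placements:
        start = int(round(p.target_telomere_distance_mb * 1e6)) + 1
        end = start + p.length_bp - 1
        at = p.target_at_fraction
        gene_probs = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
        seqs[p.chromosome][start - 1 : end] = rng.choice(
            bases, size=p.length_bp, p=gene_probs
        )
        loci.append(
            GeneLocus(
                species="synthetic",
                gene_id=p.gene_id,
                chromosome_name=p.chromosome,
                start_bp=start,
                end_bp=end,
                strand="+",
            )
        )
        truths.append(
            TruthRecord(p.gene_id, "true_telomere_distance_mb", p.target_telomere_distance_mb)
        )
        truths.append(TruthRecord(p.gene_id, "true_at_fraction", p.target_at_fraction))
    sequences = {name: arr.tobytes().decode("ascii") for name, arr in seqs.items()}
    infos = [
        ChromosomeInfo(species="synthetic", chromosome_name=name, length_bp=length)
        for name, length in spec.chromosomes
    ]
    return sequences, loci, infos, truths


# ---------------------------------------------------------------------------
# Gene-set simulation
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    n_sets: int,
    set_size: int,
    enriched_set_fold: float,
    matrix_spec: ExpressionSimSpec,
    seed: int = 0,
) -> tuple[list[GeneSet], TruthRecord]:
    """Random same-size gene sets, one of which is spiked up in AD.

    The designated set's members are appended to ``matrix_spec.spike_table``
    (the spec is modified in place) so that simulating the matrix afterwards
    realizes the enrichment.  ``enriched_set_fold = 1`` yields a pure null.
    """
    if n_sets < 2:
        raise ArgumentError(f"need >= 2 sets, got {n_sets}")
    if set_size > matrix_spec.n_genes:
        raise ArgumentError(
            f"set size {set_size} exceeds gene count {matrix_spec.n_genes}"
        )
    if enriched_set_fold < 1:
        raise ArgumentError("enriched_set_fold must be >= 1")
    rng = _subseed(seed, 2)
    width = len(str(matrix_spec.n_genes))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(matrix_spec.n_genes)]
    sets: list[GeneSet] = []
    member_indices: list[np.ndarray] = []
    for i in range(n_sets):
        idx = rng.choice(matrix_spec.n_genes, size=set_size, replace=False)
        member_indices.append(idx)
        sets.append(
            GeneSet(
                name=f"set{i + 1:03d}",
                members=tuple(gene_ids[j] for j in sorted(idx)),
                description="simulated",
            )
        )
    enriched_i = int(rng.integers(n_sets))
    if enriched_set_fold > 1:
        for j in member_indices[enriched_i]:
            matrix_spec.spike_table.append(
                Spike(gene_index=int(j), group="AD", fold=enriched_set_fold, direction="up")
            )
    truth = TruthRecord(
        entity=sets[enriched_i].name,
        prop="true_enriched_set",
        value=enriched_set_fold,
    )
    return sets, truth


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def write_truth(truths: Sequence[TruthRecord], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in truths], indent=2) + "\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(loci: Sequence[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            strand = loc.strand if loc.strand in ("+", "-") else "."
            fh.write(
                "\t".join(
                    [
                        loc.chromosome_name,
                        "fpkmkit",
                        "gene",
                        str(loc.start_bp),
                        str(loc.end_bp),
                        ".",
                        strand,
                        ".",
                        f"ID={loc.gene_id};gene_id={loc.gene_id}",
                    ]
                )
                + "\n"
            )


def write_chromosome_lengths(infos: Sequence[ChromosomeInfo], path: str | Path) -> None:
    with open(path, "w") as fh:
        for info in infos:
            fh.write(f"{info.chromosome_name}\t{info.length_bp}\n")
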