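"""Deterministic miRBase-like fixtures with known planted structure.

Generates mature FASTA, precursor GFF3, target tables and score tables in
exactly the formats :mod:`mirnet.annotation_io` consumes, with ground
truth (family membership, cluster membership, hit labels) fully determined
by the FixtureSpec and its seed, so every pipeline stage is testable
offline.

Generated ids use the species code ``syn`` to make accidental mixing with
real annotation visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from mirnet.annotation_io import (
    MatureMiRNA,
    PrecursorLocus,
    ScoreTable,
    TargetPredictionTable,
    extract_seed,
)

import pandas as pd

NUCLEOTIDES = np.array(list("ACGU"))
MATURE_LENGTH = 22
PRECURSOR_LENGTH = 80
SPECIES_CODE = "syn"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_groups`` maps group references — ``("family", i)`` or
    ``("cluster", j)``, 0-based — to the hit probability planted in that
    group; every other miRNA is a hit with ``background_hit_probability``.
    """

    rng_seed: int = 0
    family_sizes: Sequence[int] = (3, 2)
    n_singletons: int = 5
    n_genomic_clusters: int = 2
    cluster_gap_bp: int = 1_000
    inter_cluster_gap_bp: int = 200_000
    target_universe_size: int = 500
    targets_per_mirna: int = 40
    shared_target_fraction_within_family: float = 0.8
    planted_groups: Sequence[tuple[tuple[str, int], float]] = ()
    background_hit_probability: float = 0.1
    unmeasured_fraction: float = 0.0
    hit_score_threshold: float = 1.0

    @property
    def n_families(self) -> int:
        return len(self.family_sizes)

    @property
    def n_matures(self) -> int:
        return int(sum(self.family_sizes)) + self.n_singletons

    def validate(self) -> None:
        if any(s < 1 for s in self.family_sizes):
            raise ValueError("family sizes must be >= 1")
        if self.n_families + self.n_singletons > 4**6:
            raise ValueError("more distinct seeds requested than 6-mers exist")
        if self.cluster_gap_bp <= 0 or self.inter_cluster_gap_bp <= 0:
            raise ValueError("gaps must be positive")
        if self.targets_per_mirna > self.target_universe_size:
            raise ValueError("targets_per_mirna exceeds the gene universe")
        probs = [self.background_hit_probability, self.unmeasured_fraction] + [
            p for _, p in self.planted_groups
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FixtureTruth:
    """Ground truth of one generated dataset; reproducible bit-for-bit."""

    family_members: list[list[str]] = field(default_factory=list)
    cluster_members: list[list[str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)
    hit_labels: dict[str, bool] = field(default_factory=dict)
    measured: dict[str, bool] = field(default_factory=dict)
    target_sets: dict[str, list[str]] = field(default_factory=dict)

    def all_ids(self) -> list[str]:
        out = [m for fam in self.family_members for m in fam]
        out.extend(self.singletons)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as out:
            json.dump(asdict(self), out, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        with open(path, "rt", encoding="utf-8") as handle:
            return cls(**json.load(handle))


def _distinct_seeds(rng: np.random.Generator, count: int) -> list[str]:
    seeds: list[str] = []
    seen: set[str] = set()
    while len(seeds) < count:
        s = "".join(rng.choice(NUCLEOTIDES, size=6))
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return seeds


def _mature_sequence(rng: np.random.Generator, seed: str) -> str:
    head = rng.choice(NUCLEOTIDES)
    tail = "".join(rng.choice(NUCLEOTIDES, size=MATURE_LENGTH - 7))
    return f"{head}{seed}{tail}"


def generate_annotation(
    spec: FixtureSpec,
) -> tuple[list[MatureMiRNA], list[PrecursorLocus], FixtureTruth]:
    """Generate matures and loci with planted families and genomic clusters.

    Families are realized as distinct shared seeds at positions 2-7 of
    otherwise random 22-mers.  Genomic clusters are runs of consecutive
    loci with intra-cluster gaps strictly below ``cluster_gap_bp`` and
    inter-cluster gaps above ``inter_cluster_gap_bp``; matures are dealt
    to clusters round-robin so family and cluster structure stay
    decoupled.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    truth = FixtureTruth()
    seeds = _distinct_seeds(rng, spec.n_families + spec.n_singletons)
    matures: list[MatureMiRNA] = []
    for fam_idx, size in enumerate(spec.family_sizes):
        members: list[str] = []
        for member_idx in range(size):
            name = f"{SPECIES_CODE}-miR-f{fam_idx + 1}{chr(ord('a') + member_idx)}-5p"
            seq = _mature_sequence(rng, seeds[fam_idx])
            matures.append(
                MatureMiRNA(name, SPECIES_CODE, seq, extract_seed(seq))
            )
            members.append(name)
        truth.family_members.append(members)
    for singleton_idx in range(spec.n_singletons):
        name = f"{SPECIES_CODE}-miR-s{singleton_idx + 1}-3p"
        seq = _mature_sequence(rng, seeds[spec.n_families + singleton_idx])
        matures.append(MatureMiRNA(name, SPECIES_CODE, seq, extract_seed(seq)))
        truth.singletons.append(name)

    # Deal matures to genomic clusters round-robin, then lay each cluster
    # down as a run of loci separated by sub-threshold gaps.
    n_clusters = max(1, spec.n_genomic_clusters)
    buckets: list[list[MatureMiRNA]] = [[] for _ in range(n_clusters)]
    for i, m in enumerate(matures):
        buckets[i % n_clusters].append(m)
    loci: list[PrecursorLocus] = []
    chrom = "chr1"
    cursor = 10_000
    for cluster_idx, bucket in enumerate(buckets):
        members = []
        for m in bucket:
            gap = int(rng.integers(1, max(2, spec.cluster_gap_bp)))  # < cluster_gap_bp
            if members:
                cursor += gap
            start = cursor
            end = start + PRECURSOR_LENGTH
            precursor_id = f"{SPECIES_CODE}-mir-{m.id.split('-')[2]}"
            loci.append(
                PrecursorLocus(
                    id=precursor_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    mature_ids=[m.id],
                )
            )
            m.precursor_ids.append(precursor_id)
            members.append(m.id)
            cursor = end
        truth.cluster_members.append(members)
        cursor += spec.inter_cluster_gap_bp + int(rng.integers(1, 10_000))
    return matures, loci, truth


def generate_targets(spec: FixtureSpec, truth: FixtureTruth) -> TargetPredictionTable:
    """Target sets with high within-family and low between-family overlap.

    Each family owns a disjoint pool of genes; members draw
    ``shared_target_fraction_within_family`` of their targets from the
    pool and the remainder uniformly from the whole universe.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed + 1)
    universe = [f"g{i:06d}" for i in range(spec.target_universe_size)]
    n_shared = int(round(spec.shared_target_fraction_within_family * spec.targets_per_mirna))
    pool_cursor = 0
    targets: dict[str, set[str]] = {}
    for members in truth.family_members:
        pool = universe[pool_cursor : pool_cursor + n_shared]
        pool_cursor += n_shared
        if len(pool) < n_shared:
            raise ValueError("gene universe too small for the requested family pools")
        for member in members:
            chosen = set(pool)
            while len(chosen) < spec.targets_per_mirna:
                chosen.add(universe[int(rng.integers(0, len(universe)))])
            targets[member] = chosen
    for member in truth.singletons:
        chosen: set[str] = set()
        while len(chosen) < spec.targets_per_mirna:
            chosen.add(universe[int(rng.integers(0, len(universe)))])
        targets[member] = chosen
    truth.target_sets = {k: sorted(v) for k, v in targets.items()}
    return TargetPredictionTable("synthetic", targets)


def _group_members(spec: FixtureSpec, truth: FixtureTruth, ref: tuple[str, int]) -> list[str]:
    kind, index = ref
    if kind == "family":
        return truth.family_members[index]
    if kind == "cluster":
        return truth.cluster_members[index]
    raise ValueError(f"unknown group kind {kind!r}")


def generate_scores(spec: FixtureSpec, truth: FixtureTruth) -> ScoreTable:
    """Score table whose hit rule ``score > threshold`` recovers the planted labels.

    Hit labels are drawn per miRNA with the planted group's probability
    (background elsewhere); hit scores land strictly above the threshold,
    non-hit scores strictly below.  An ``expression`` column marks an
    ``unmeasured_fraction`` of miRNAs as unexpressed (reads <= 10).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed + 2)
    hit_prob: dict[str, float] = {m: spec.background_hit_probability for m in truth.all_ids()}
    for ref, prob in spec.planted_groups:
        for member in _group_members(spec, truth, ref):
            hit_prob[member] = prob
    thr = spec.hit_score_threshold
    rows = []
    for mirna_id in truth.all_ids():
        is_hit = bool(rng.random() < hit_prob[mirna_id])
        measured = bool(rng.random() >= spec.unmeasured_fraction)
        if is_hit:
            score = thr + 0.5 + 1.5 * rng.random()
        else:
            score = thr - 0.5 - 1.5 * rng.random()
        truth.hit_labels[mirna_id] = is_hit
        truth.measured[mirna_id] = measured
        reads = float(11 + rng.integers(0, 1000)) if measured else float(rng.integers(0, 10))
        rows.append((mirna_id, score, reads))
    df = pd.DataFrame(rows, columns=["mirna_id", "score", "expression"]).set_index("mirna_id")
    return ScoreTable(data=df)


def write_fixture_files(
    spec: FixtureSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Generate everything and write FASTA/GFF3/TSV/JSON files to a directory.

    Returns the paths keyed by artifact name.  Byte-identical across runs
    with the same spec.
    """
    from mirnet.annotation_io import write_locus_gff3, write_mature_fasta, write_target_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matures, loci, truth = generate_annotation(spec)
    targets = generate_targets(spec, truth)
    scores = generate_scores(spec, truth)
    paths = {
        "fasta": out_dir / "mature.fa",
        "gff3": out_dir / "loci.gff3",
        "targets": out_dir / "targets.tsv",
        "scores": out_dir / "scores.tsv",
        "truth": out_dir / "truth.json",
    }
    write_mature_fasta(matures, paths["fasta"])
    write_locus_gff3(loci, paths["gff3"])
    write_target_table(targets, paths["targets"])
    scores.data.reset_index().to_csv(paths["scores"], sep="\t", index=False, float_format="%.6f")
    truth.to_json(paths["truth"])
    return paths
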