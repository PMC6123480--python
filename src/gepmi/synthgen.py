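"""Synthetic metagenome cohorts with controllable individual signal.

Each individual carries private strain-level variants: every species has an
ancestral genome, a fixed core fraction identical across individuals, and
individual-private substitutions sprinkled over the non-core fraction.
A visit draws species abundances from a Dirichlet, mixes them with the
previous visit's abundances (temporal drift), and samples error-laden reads
from the individual's genomes.  Because long k-mers overlapping a private
variant are unique to that individual, intra-individual Jaccard similarity
exceeds inter-individual similarity by a margin controlled by the SNP rate
and core fraction — the statistical structure the identification test
relies on.  Setting ``core_fraction=1`` with ``snp_rate=0`` produces a
*null* cohort in which individuals are statistically indistinguishable.

Perturbation modes emulate longitudinal disturbances: ``antibiotic_like``
suppresses a random subset of species at later visits; ``replace`` swaps in
a foreign individual's genomes (a negative control for identification).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .identify import CohortMap
from .sketch import SequenceSample

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the standard *signal* cohort: 12 individuals sampled
    at 3 visits, 5 species of 100 kb, 70% core genome, private substitutions
    at 0.5% on the non-core fraction, 150 bp reads with 0.5% error, and
    about 2 Mb of sequence per sample.
    """

    n_individuals: int = 12
    samples_per_individual: int = 3
    n_species: int = 5
    genome_length: int = 100_000
    core_fraction: float = 0.7
    snp_rate: float = 0.005
    read_length: int = 150
    s_bases: int = 2_000_000
    error_rate: float = 0.005
    abundance_concentration: float = 5.0
    drift: float = 0.1
    perturbation: str = "none"  # none | antibiotic_like | replace
    perturb_from_visit: int = 1  # 0-based visit index where perturbation starts
    perturb_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        for name in ("snp_rate", "error_rate", "drift", "perturb_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.perturbation not in ("none", "antibiotic_like", "replace"):
            raise ValueError(f"unknown perturbation mode {self.perturbation!r}")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def null_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """A cohort with no individual signal: all genomes identical.

    Sized so every target's null is fitted on 30 inter-individual values
    (16 individuals x 2 visits) while staying cheap to simulate.
    """
    base = dict(
        n_individuals=16,
        samples_per_individual=2,
        n_species=3,
        genome_length=50_000,
        core_fraction=1.0,
        snp_rate=0.0,
        s_bases=300_000,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticCohortConfig(**base)


def _mutate(genome: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> None:
    """Substitute bases in place at the given sites (never the same base)."""
    if sites.size:
        genome[sites] = (genome[sites] + rng.integers(1, 4, size=sites.size)) % 4


def generate_individual_genomes(
    config: SyntheticCohortConfig, rng: np.random.Generator | None = None
) -> dict[str, list[np.ndarray]]:
    """Per-individual genome sets as 2-bit code arrays.

    One ancestral genome per species; each individual receives a copy with
    private substitutions at ``snp_rate`` restricted to the non-core
    positions.  Core positions are identical across all individuals.
    """
    if config.core_fraction == 1.0 and config.snp_rate > 0:
        warnings.warn(
            "core_fraction=1 leaves no room for private variants; "
            "individuals will be indistinguishable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ancestors = [
        rng.integers(0, 4, size=config.genome_length, dtype=np.uint8)
        for _ in range(config.n_species)
    ]
    noncore_masks = [
        rng.random(config.genome_length) >= config.core_fraction
        for _ in range(config.n_species)
    ]
    genomes: dict[str, list[np.ndarray]] = {}
    for i in range(config.n_individuals):
        individual_id = f"I{i:02d}"
        own = []
        for anc, mask in zip(ancestors, noncore_masks):
            g = anc.copy()
            candidates = np.flatnonzero(mask)
            hit = candidates[rng.random(candidates.size) < config.snp_rate]
            _mutate(g, hit, rng)
            own.append(g)
        genomes[individual_id] = own
    return genomes


def _draw_reads(
    genome: np.ndarray, count: int, config: SyntheticCohortConfig, rng: np.random.Generator
) -> list[str]:
    """Sample reads at uniform positions with i.i.d. substitution errors."""
    if count == 0:
        return []
    rl = config.read_length
    pos = rng.integers(0, genome.size - rl + 1, size=count)
    reads = genome[pos[:, None] + np.arange(rl)]
    if config.error_rate > 0:
        err = rng.random(reads.shape) < config.error_rate
        shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
        reads = np.where(err, (reads + shift) % 4, reads)
    # random strand: reverse-complement half of the reads
    flip = rng.random(count) < 0.5
    reads[flip] = (3 - reads[flip])[:, ::-1]
    chars = _BASES[reads]
    return [row.tobytes().decode("ascii") for row in chars]


def sample_metagenome(
    genomes: list[np.ndarray],
    visit: int,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    prev_abundances: np.ndarray | None = None,
    dropped_species: np.ndarray | None = None,
    sample_id: str = "",
    individual_id: str = "",
) -> tuple[SequenceSample, np.ndarray]:
    """Reads for one visit, plus the abundance vector actually used.

    Fresh Dirichlet abundances are blended with the previous visit's by
    weight ``1 − drift``; species listed in ``dropped_species`` contribute
    no reads (abundances renormalised).
    """
    fresh = rng.dirichlet([config.abundance_concentration] * config.n_species)
    if prev_abundances is None:
        abundances = fresh
    else:
        abundances = (1.0 - config.drift) * prev_abundances + config.drift * fresh
    effective = abundances.copy()
    if dropped_species is not None and len(dropped_species):
        effective[np.asarray(dropped_species, dtype=int)] = 0.0
        if effective.sum() == 0:
            raise ValueError("perturbation dropped every species")
        effective = effective / effective.sum()
    n_reads = -(-config.s_bases // config.read_length)  # ceil
    per_species = rng.multinomial(n_reads, effective)
    reads: list[str] = []
    for genome, count in zip(genomes, per_species):
        reads.extend(_draw_reads(genome, int(count), config, rng))
    sample = SequenceSample(
        sample_id=sample_id or f"{individual_id}_V{visit}",
        individual_id=individual_id or None,
        reads=reads,
    )
    return sample, abundances


@dataclass
class SyntheticCohort:
    """A generated cohort: samples, ground-truth table and cohort map."""

    samples: list[SequenceSample]
    truth: pd.DataFrame  # sample_id individual_id visit perturbed
    config: SyntheticCohortConfig

    def cohort_map(self) -> CohortMap:
        return CohortMap(
            entries=dict(zip(self.truth["sample_id"], self.truth["individual_id"])),
            visits=dict(zip(self.truth["sample_id"], self.truth["visit"].astype(str))),
        )


def generate_cohort(
    config: SyntheticCohortConfig,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate the full cohort; optionally write FASTA + truth TSV + config.

    Fully deterministic under ``config.seed``.  When ``out_dir`` is given,
    one FASTA file per sample is written alongside ``truth.tsv`` and
    ``config.json``; pre-existing read files raise an error rather than
    being overwritten.
    """
    rng = np.random.default_rng(config.seed)
    genomes = generate_individual_genomes(config, rng=rng)
    foreign = None
    if config.perturbation == "replace":
        foreign_cfg = SyntheticCohortConfig(
            **{**asdict(config), "n_individuals": config.n_individuals, "perturbation": "none"}
        )
        foreign = generate_individual_genomes(foreign_cfg, rng=rng)

    per_individual = config.samples_per_individual
    if isinstance(per_individual, int):
        visits_of = {ind: per_individual for ind in genomes}
    else:
        visits_of = {
            ind: per_individual[i] for i, ind in enumerate(genomes)
        }

    samples: list[SequenceSample] = []
    rows = []
    for ind, own_genomes in genomes.items():
        prev = None
        for visit in range(visits_of[ind]):
            perturbed = (
                config.perturbation != "none" and visit >= config.perturb_from_visit
            )
            dropped = None
            use_genomes = own_genomes
            if perturbed and config.perturbation == "antibiotic_like":
                n_drop = int(round(config.perturb_fraction * config.n_species))
                dropped = rng.choice(config.n_species, size=n_drop, replace=False)
            elif perturbed and config.perturbation == "replace":
                use_genomes = foreign[ind]
            sample, prev = sample_metagenome(
                use_genomes,
                visit,
                config,
                rng,
                prev_abundances=prev,
                dropped_species=dropped,
                sample_id=f"{ind}_V{visit}",
                individual_id=ind,
            )
            samples.append(sample)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "individual_id": ind,
                    "visit": visit,
                    "perturbed": bool(perturbed),
                }
            )
    truth = pd.DataFrame(rows)
    cohort = SyntheticCohort(samples=samples, truth=truth, config=config)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample in cohort.samples:
        path = out_dir / f"{sample.sample_id}.fasta"
        if path.exists():
            raise FileExistsError(f"refusing to overwrite {path}")
        with open(path, "w") as fh:
            for i, read in enumerate(sample.reads):
                fh.write(f">{sample.sample_id}_r{i}\n{read}\n")
    cohort.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    (out_dir / "config.json").write_text(cohort.config.to_json())
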