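"""Synthetic two-cohort generator for circular/linear RNA analysis.

Generates gene, back-splice junction (BSJ) and forward-splice junction
(FSJ) count matrices, sample metadata and a ground-truth record with the
statistical structure the downstream analysis assumes: negative-binomial
counts around log-normal per-feature means, BSJ abundance coupled to the
host gene, a tunable global depression of circRNA levels in cases
(``global_circ_log2fc``, written :math:`\\delta`), sparse linear-RNA
effects, a technical batch shift and per-sample library-size scatter.

Default cohort sizes follow the discovery (259 cases / 161 controls) and
replication (48 / 48) designs of the blood study the pipeline emulates.
Junction coordinates live on a toy genome (``chrS1`` ...), since real
coordinates are irrelevant to the statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from circimbalance.containers import CountMatrix
from circimbalance.junction_catalog import JunctionId

_STAGE_COHORT = 0
_STAGE_TOOLS = 1
_STAGE_STRUCTURE = 2

TOOLS = ("toolA", "toolB", "toolC")


def _rng(seed: int, stage: int) -> np.random.Generator:
    # Sub-streams derived deterministically per stage so stages can be
    # re-run in isolation from the same root seed.
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Attributes
    ----------
    n_cases, n_controls
        Cohort sizes; defaults follow the discovery cohort design.
    n_genes, n_bsj
        Number of gene features and of simulated BSJs. Each BSJ is
        assigned one host gene; two flanking FSJs are generated per BSJ.
    mean_log_expression, mean_log_sd
        Per-feature log2 mean expression is drawn from a normal with
        this centre and spread.
    dispersion
        Negative-binomial dispersion applied per feature (variance
        mu + dispersion * mu^2).
    circ_fraction
        Expected BSJ reads as a fraction of host-gene reads.
    global_circ_log2fc
        Additive shift (delta) on log2 BSJ means in cases; negative
        values encode a global circRNA reduction.
    de_gene_fraction, de_gene_log2fc
        Fraction of genes given a case/control effect of the stated
        magnitude (random sign); propagates to hosted junctions.
    batch_log2fc
        Additive log2 shift on a random half of the features for
        samples in the second technical batch.
    library_size_spread
        SD (log2 scale) of per-sample library scaling factors.
    fsj_fraction
        Expected FSJ reads as a fraction of host-gene reads.
    fp_rate_per_tool, tool_sensitivity
        Behaviour of the pseudo detection tools.
    """

    n_cases: int = 259
    n_controls: int = 161
    n_genes: int = 16000
    n_bsj: int = 400
    mean_log_expression: float = 7.0
    mean_log_sd: float = 1.5
    dispersion: float = 0.2
    circ_fraction: float = 0.1
    global_circ_log2fc: float = -0.5
    de_gene_fraction: float = 0.05
    de_gene_log2fc: float = 0.5
    batch_log2fc: float = 0.2
    library_size_spread: float = 0.2
    fsj_fraction: float = 0.5
    fp_rate_per_tool: float = 0.05
    tool_sensitivity: float = 0.95
    seed: int = 0
    structure_seed: int | None = None  # share feature space across cohorts

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_bsj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("n_cases and n_controls must both be at least 2")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if not (0 < self.circ_fraction <= 1):
            raise ValueError(f"circ_fraction must be in (0, 1], got {self.circ_fraction}")
        if not (0 <= self.de_gene_fraction < 1):
            raise ValueError(
                f"de_gene_fraction must be in [0, 1), got {self.de_gene_fraction}"
            )
        if self.library_size_spread < 0:
            raise ValueError(
                f"library_size_spread must be >= 0, got {self.library_size_spread}"
            )
        if not (0 <= self.fp_rate_per_tool < 1):
            raise ValueError(
                f"fp_rate_per_tool must be in [0, 1), got {self.fp_rate_per_tool}"
            )
        if not (0 < self.tool_sensitivity <= 1):
            raise ValueError(
                f"tool_sensitivity must be in (0, 1], got {self.tool_sensitivity}"
            )
        if not (0 < self.fsj_fraction <= 1):
            raise ValueError(f"fsj_fraction must be in (0, 1], got {self.fsj_fraction}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**values)


@dataclass
class GroundTruth:
    """What the generator actually did, for downstream validation."""

    true_bsj_set: set[JunctionId]
    true_log2fc: pd.Series  # per feature (genes, BSJs, FSJs), case vs control
    library_factors: pd.Series  # per sample
    host_map: dict[str, str] = field(default_factory=dict)  # BSJ string -> gene id


@dataclass
class CohortData:
    """One simulated cohort: counts, metadata, annotation and truth."""

    gene_counts: CountMatrix
    bsj_counts: CountMatrix
    fsj_counts: CountMatrix
    samples: pd.DataFrame
    gene_model: pd.DataFrame
    truth: GroundTruth
    config: "SimulationConfig | None" = None


def _gene_layout(n_genes: int, n_bsj: int) -> pd.DataFrame:
    # Non-overlapping gene spans on one toy chromosome, long enough to
    # place every BSJ strictly inside its host.
    span = max(5000, 2 * n_bsj + 1200)
    # leave room upstream so flanking FSJs never get non-positive coordinates
    starts = 5001 + np.arange(n_genes) * (span + 5000)
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": "chrS1",
            "start": starts,
            "end": starts + span - 1,
            "strand": strands,
        }
    )


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Draw one cohort of gene/BSJ/FSJ counts with known ground truth.

    Counts are negative binomial with per-feature log-normal means. The
    per-sample mean of a BSJ is ``circ_fraction`` times its host gene's
    mean, times ``2**delta`` in cases; flanking FSJ means are
    ``fsj_fraction`` times the host mean with no delta, so host-gene
    effects propagate to both junction types but the global circRNA
    shift touches BSJs only. Identical seeds give bit-identical output.

    Feature-level structure (per-feature means, which genes carry
    effects, host assignment, coordinates) is drawn from a separate
    stream seeded by ``structure_seed`` (default: ``seed``), so a
    discovery and a replication cohort generated with the same
    structure seed share one feature space while drawing independent
    samples.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_COHORT)
    structure_seed = config.seed if config.structure_seed is None else config.structure_seed
    rng_struct = _rng(structure_seed, _STAGE_STRUCTURE)
    n = config.n_cases + config.n_controls

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    case = np.r_[np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "group": np.where(case == 1, "PD", "Control"),
            "sex": rng.choice(["M", "F"], size=n),
            "age": np.round(rng.normal(65.0, 8.0, size=n), 1),
            "batch": np.arange(n) % 2,
        }
    ).set_index("sample")

    gene_model = _gene_layout(config.n_genes, config.n_bsj)
    gene_ids = gene_model["gene_id"].tolist()

    log2_mean = rng_struct.normal(
        config.mean_log_expression, config.mean_log_sd, config.n_genes
    )

    gene_lfc = np.zeros(config.n_genes)
    n_de = int(round(config.de_gene_fraction * config.n_genes))
    if n_de > 0 and config.de_gene_log2fc != 0.0:
        de_idx = rng_struct.choice(config.n_genes, size=n_de, replace=False)
        signs = rng_struct.choice([-1.0, 1.0], size=n_de)
        gene_lfc[de_idx] = signs * config.de_gene_log2fc

    batch_affected = rng_struct.random(config.n_genes) < 0.5
    batch_eff = np.where(batch_affected, config.batch_log2fc, 0.0)

    lib_log2 = rng.normal(0.0, config.library_size_spread, size=n)
    lib = 2.0 ** lib_log2

    batch = samples["batch"].to_numpy()
    # log2 mean per gene and sample: base + case effect + batch shift + library
    log2_mu_gene = (
        log2_mean[:, None]
        + gene_lfc[:, None] * case[None, :]
        + batch_eff[:, None] * batch[None, :]
        + lib_log2[None, :]
    )
    mu_gene = 2.0 ** log2_mu_gene

    hosts = rng_struct.integers(0, config.n_genes, size=config.n_bsj)
    gene_start = gene_model["start"].to_numpy()
    gene_strand = gene_model["strand"].to_numpy()

    bsj_ids = []
    fsj_ids = []
    host_map: dict[str, str] = {}
    for j, h in enumerate(hosts):
        start = int(gene_start[h]) + 100 + 2 * j
        end = start + 500
        strand = gene_strand[h]
        b = JunctionId("chrS1", start, end, strand, kind="BSJ")
        bsj_ids.append(b)
        fsj_ids.append(JunctionId("chrS1", start - 200, start, strand, kind="FSJ"))
        fsj_ids.append(JunctionId("chrS1", end, end + 200, strand, kind="FSJ"))
        host_map[str(b)] = gene_ids[h]

    delta = config.global_circ_log2fc
    mu_bsj = config.circ_fraction * mu_gene[hosts] * 2.0 ** (delta * case[None, :])
    mu_fsj = np.repeat(config.fsj_fraction * mu_gene[hosts], 2, axis=0)

    alpha = config.dispersion

    def _nb(mu: np.ndarray) -> np.ndarray:
        size = 1.0 / alpha
        p = size / (size + mu)
        return rng.negative_binomial(size, p)

    gene_counts = pd.DataFrame(_nb(mu_gene), index=gene_ids, columns=sample_ids)
    bsj_index = [str(b) for b in bsj_ids]
    fsj_index = [str(f) for f in fsj_ids]
    bsj_counts = pd.DataFrame(_nb(mu_bsj), index=bsj_index, columns=sample_ids)
    fsj_counts = pd.DataFrame(_nb(mu_fsj), index=fsj_index, columns=sample_ids)

    bsj_lfc = gene_lfc[hosts] + delta
    fsj_lfc = np.repeat(gene_lfc[hosts], 2)
    true_log2fc = pd.Series(
        np.r_[gene_lfc, bsj_lfc, fsj_lfc],
        index=gene_ids + bsj_index + fsj_index,
    )

    truth = GroundTruth(
        true_bsj_set=set(bsj_ids),
        true_log2fc=true_log2fc,
        library_factors=pd.Series(lib, index=sample_ids),
        host_map=host_map,
    )
    return CohortData(
        gene_counts=CountMatrix(gene_counts, "gene"),
        bsj_counts=CountMatrix(bsj_counts, "BSJ"),
        fsj_counts=CountMatrix(fsj_counts, "FSJ"),
        samples=samples,
        gene_model=gene_model,
        truth=truth,
        config=config,
    )


def simulate_tool_calls(
    true_bsj: set[JunctionId],
    bsj_counts: "CountMatrix | pd.DataFrame",
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Emulate three BSJ detection tools run over the same cohort.

    Each pseudo-tool reports an independent Bernoulli(``tool_sensitivity``)
    subset of the true BSJs, with the true read counts, plus spurious
    junctions private to that tool at rate ``fp_rate_per_tool`` (relative
    to the true catalogue size). Spurious junctions are placed on
    tool-specific chromosomes so they can never collide with true
    coordinates, and receive low Poisson counts.
    """
    config.validate()
    rng = _rng(config.seed, _STAGE_TOOLS)
    frame = bsj_counts.data if isinstance(bsj_counts, CountMatrix) else bsj_counts
    junctions = sorted(true_bsj)
    sample_cols = list(frame.columns)

    calls: dict[str, pd.DataFrame] = {}
    for tool in TOOLS:
        detected = rng.random(len(junctions)) < config.tool_sensitivity
        rows = []
        for j, hit in zip(junctions, detected):
            if not hit:
                continue
            counts = frame.loc[str(j)]
            rows.append([j.chrom, j.start, j.end, j.strand, *counts.tolist()])
        n_fp = rng.binomial(len(junctions), config.fp_rate_per_tool)
        for i in range(n_fp):
            start = 1000 * i + 1
            fp_counts = rng.poisson(1.0, size=len(sample_cols))
            rows.append([f"chrFP_{tool}", start, start + 500, "+", *fp_counts.tolist()])
        calls[tool] = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", *sample_cols])
    return calls
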