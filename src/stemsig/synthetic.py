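"""Synthetic data with the statistical structure the analysis pipeline assumes.

The single-cell generator draws negative-binomial counts with log-normal
gene means, cluster structure, planted up-regulated gene programs of
controllable log2 effect size, per-cell library-size variation,
mitochondrial genes, and designated QC-failure cells (low-complexity,
high-mitochondrial, doublets).  Companion generators produce cell-cycle
program structure with a quiescent subpopulation, a bulk tumor cohort with
a signature-positive subgroup carrying a planted hazard ratio, and
single-hit Poisson limiting-dilution outcomes.

All randomness flows from the one root seed through ``numpy``'s
``SeedSequence`` spawning, so identical configurations reproduce outputs
bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .signatures import GeneSignature

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_counts",
    "simulate_cycle_programs",
    "simulate_cohort",
    "simulate_limiting_dilution",
]


@dataclass
class SimConfig:
    """Configuration of the single-cell count simulation.

    Program genes are allocated automatically (disjoint blocks of
    ``program_size`` non-mitochondrial genes per program named in
    ``program_assignments``) unless ``program_genes`` names them explicitly.
    ``qc_min_genes`` / ``qc_max_mito`` are the thresholds against which the
    designated QC-failure cells are constructed.
    """

    n_genes: int = 3000
    n_cells: int = 3000
    n_clusters: int = 4
    cluster_proportions: Optional[list] = None
    program_assignments: dict = field(default_factory=dict)  # cluster -> [program]
    program_log2_effect: dict = field(default_factory=dict)  # program -> log2 FC
    program_genes: dict = field(default_factory=dict)  # program -> [gene name]
    program_size: int = 100
    baseline_mean_log_mu: float = math.log(5.0)
    baseline_mean_log_sigma: float = 0.5
    nb_dispersion: float = 0.2
    lib_size_sigma: float = 0.3
    mito_fraction_genes: float = 0.05
    n_lowdepth_cells: int = 0
    n_highmito_cells: int = 0
    n_doublets: int = 0
    qc_min_genes: int = 2000
    qc_max_mito: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_cells <= 0:
            raise ValueError("n_genes and n_cells must be positive")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.n_clusters] * self.n_clusters
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters:
            raise ValueError("cluster_proportions length != n_clusters")
        if abs(props.sum() - 1.0) > 1e-9 or (props < 0).any():
            raise ValueError("cluster_proportions must be a simplex vector")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.mito_fraction_genes < 1):
            raise ValueError("mito_fraction_genes must be in [0, 1)")
        for v in (self.n_lowdepth_cells, self.n_highmito_cells, self.n_doublets):
            if v < 0:
                raise ValueError("cell counts must be non-negative")
        if self.n_lowdepth_cells + self.n_highmito_cells > self.n_cells:
            raise ValueError("more designated QC failures than cells")
        for prog in {p for ps in self.program_assignments.values() for p in ps}:
            self.program_log2_effect.setdefault(prog, 0.0)
        for e in self.program_log2_effect.values():
            if e < 0:
                raise ValueError("program_log2_effect must be >= 0")


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth for a simulated experiment."""

    barcodes: np.ndarray
    true_cluster: np.ndarray  # int; doublets inherit their first parent's cluster
    qc_fail: np.ndarray  # none | lowdepth | highmito | doublet
    program_genes: dict  # program -> [gene name]
    phase: Optional[np.ndarray] = None  # G1 | S | G2M when cycle programs enabled

    def doublet_labels(self) -> np.ndarray:
        return self.qc_fail == "doublet"

    def expected_removed(self) -> set:
        return set(self.barcodes[self.qc_fail != "none"])

    def signature(self, program: str) -> GeneSignature:
        return GeneSignature(
            name=program,
            genes=list(self.program_genes[program]),
            direction="up",
            provenance="planted simulation program",
        )


def _gene_universe(config: SimConfig, reserved_names=()):
    """Gene names, mito flags and per-gene baseline means.

    Reserved names (e.g. cell-cycle program symbols) replace the leading
    non-mitochondrial default names so callers can plant known symbols.
    """
    n_mito = int(round(config.mito_fraction_genes * config.n_genes))
    names = [f"MT-SIM{i + 1}" for i in range(n_mito)]
    n_rest = config.n_genes - n_mito
    reserved = list(reserved_names)
    if len(reserved) > n_rest:
        raise ValueError("more reserved gene names than non-mito genes")
    names += reserved
    names += [f"GENE{i + 1:05d}" for i in range(n_rest - len(reserved))]
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[:n_mito] = True
    return np.array(names, dtype=object), mito


def _allocate_programs(config: SimConfig, gene_names, mito_flag,
                       reserved=()) -> dict:
    programs = {p for ps in config.program_assignments.values() for p in ps}
    out = dict(config.program_genes)
    universe = set(gene_names)
    for p, genes in out.items():
        missing = [g for g in genes if g not in universe]
        if missing:
            raise ValueError(f"program {p!r} genes not in universe: {missing[:5]}")
    reserved = set(reserved)
    candidates = [g for g, m in zip(gene_names, mito_flag)
                  if not m and g not in reserved]
    taken = {g for genes in out.values() for g in genes}
    pool = [g for g in candidates if g not in taken]
    for p in sorted(programs):
        if p in out:
            continue
        if len(pool) < config.program_size:
            raise ValueError("gene universe too small for requested programs")
        out[p] = pool[: config.program_size]
        pool = pool[config.program_size:]
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial via gamma-Poisson; var = m + dispersion * m^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _simulate_engine(config: SimConfig, reserved_names=(),
                     cell_multiplier_fn=None):
    """Core generator; ``cell_multiplier_fn(rng, clusters, gene_names)`` may
    return (per-cell-per-gene multiplier matrix or None, phase array)."""
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    rng_assign, rng_mu, rng_lib, rng_counts, rng_qc, rng_doublet = rngs

    gene_names, mito_flag = _gene_universe(config, reserved_names)
    program_genes = _allocate_programs(config, gene_names, mito_flag,
                                       reserved=reserved_names)
    gene_pos = {g: i for i, g in enumerate(gene_names)}

    clusters = rng_assign.choice(
        config.n_clusters, size=config.n_cells, p=config.cluster_proportions
    )
    mu_g = rng_mu.lognormal(
        config.baseline_mean_log_mu, config.baseline_mean_log_sigma,
        size=config.n_genes,
    )
    lib = rng_lib.lognormal(0.0, config.lib_size_sigma, size=config.n_cells)

    # per-cluster fold-change rows for planted programs
    fold = np.ones((config.n_genes, config.n_clusters))
    for cl, progs in config.program_assignments.items():
        for p in progs:
            idx = [gene_pos[g] for g in program_genes[p]]
            fold[idx, cl] *= 2.0 ** config.program_log2_effect[p]

    mean = mu_g[:, None] * fold[:, clusters] * lib[None, :]

    phase = None
    if cell_multiplier_fn is not None:
        mult, phase = cell_multiplier_fn(rng_assign, clusters, gene_names)
        if mult is not None:
            mean = mean * mult

    counts = _nb_draw(rng_counts, mean, config.nb_dispersion)

    qc_fail = np.array(["none"] * config.n_cells, dtype=object)
    # designated high-mito cells: inflate mitochondrial reads to twice the
    # QC fraction (capped) while leaving complexity intact
    n_hm = config.n_highmito_cells
    hm_idx = np.arange(config.n_cells - config.n_lowdepth_cells - n_hm,
                       config.n_cells - config.n_lowdepth_cells)
    target = min(2.0 * config.qc_max_mito, 0.9)
    mito_rows = np.flatnonzero(mito_flag)
    if n_hm and len(mito_rows) == 0:
        raise ValueError("cannot plant high-mito cells without mito genes")
    for c in hm_idx:
        nonmito_total = counts[~mito_flag, c].sum()
        need = int(math.ceil(target / (1 - target) * max(nonmito_total, 1)))
        add = rng_qc.multinomial(need, np.ones(len(mito_rows)) / len(mito_rows))
        counts[mito_rows, c] = add
        qc_fail[c] = "highmito"
    # designated low-depth cells: keep only half the QC gene threshold
    ld_idx = np.arange(config.n_cells - config.n_lowdepth_cells, config.n_cells)
    for c in ld_idx:
        expressed = np.flatnonzero(counts[:, c] > 0)
        keep_n = max(1, min(config.qc_min_genes // 2, len(expressed)))
        keep = rng_qc.choice(expressed, size=keep_n, replace=False)
        mask = np.ones(config.n_genes, dtype=bool)
        mask[keep] = False
        counts[mask, c] = 0
        qc_fail[c] = "lowdepth"

    barcodes = [f"CELL{i + 1:06d}" for i in range(config.n_cells)]
    true_cluster = clusters.copy()

    if config.n_doublets:
        normal = np.flatnonzero(qc_fail == "none")
        pairs = rng_doublet.choice(normal, size=(config.n_doublets, 2))
        dbl = counts[:, pairs[:, 0]] + counts[:, pairs[:, 1]]
        counts = np.concatenate([counts, dbl], axis=1)
        barcodes += [f"DBL{i + 1:04d}" for i in range(config.n_doublets)]
        true_cluster = np.concatenate([true_cluster, clusters[pairs[:, 0]]])
        qc_fail = np.concatenate(
            [qc_fail, np.array(["doublet"] * config.n_doublets, dtype=object)]
        )
        if phase is not None:
            phase = np.concatenate(
                [phase, np.array(["doublet"] * config.n_doublets, dtype=object)]
            )

    cm = CountMatrix(
        values=counts.astype(np.int64),
        gene_names=gene_names,
        barcodes=np.array(barcodes, dtype=object),
        mito_flag=mito_flag,
    )
    gt = GroundTruth(
        barcodes=np.array(barcodes, dtype=object),
        true_cluster=true_cluster,
        qc_fail=qc_fail,
        program_genes=program_genes,
        phase=phase,
    )
    return cm, gt


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate a gene x cell count matrix with planted cluster programs."""
    return _simulate_engine(config)


def simulate_cycle_programs(
    config: SimConfig,
    s_genes,
    g2m_genes,
    carrier_fraction: float,
    effect_log2: float = 2.0,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate counts with S/G2M proliferation programs.

    A ``carrier_fraction`` of cells is proliferative, split evenly between
    an S-program-on state and a G2M-program-on state (program-gene means
    multiplied by ``2**effect_log2``); the remaining quiescent cells express
    neither program above baseline.  ``carrier_fraction`` may be a scalar or
    a per-cluster sequence (length ``n_clusters``), which plants quiescent
    clusters.  True phases are recorded in the ground truth.
    """
    s_genes, g2m_genes = list(s_genes), list(g2m_genes)
    if not s_genes or not g2m_genes:
        raise ValueError("S and G2M gene lists must be nonempty")
    if set(s_genes) & set(g2m_genes):
        raise ValueError("S and G2M gene lists overlap")
    frac = np.atleast_1d(np.asarray(carrier_fraction, dtype=float))
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("carrier_fraction must be in [0, 1]")
    if len(frac) not in (1, config.n_clusters):
        raise ValueError("carrier_fraction must be scalar or one per cluster")

    def add_cycle(rng, clusters, gene_names):
        pos = {g: i for i, g in enumerate(gene_names)}
        s_idx = np.array([pos[g] for g in s_genes], dtype=int)
        g_idx = np.array([pos[g] for g in g2m_genes], dtype=int)
        n = len(clusters)
        u = rng.random(n)
        phase = np.array(["G1"] * n, dtype=object)
        cell_frac = frac[0] if len(frac) == 1 else frac[clusters]
        carrier = u < cell_frac
        half = rng.random(n) < 0.5
        phase[carrier & half] = "S"
        phase[carrier & ~half] = "G2M"
        mult = np.ones((len(gene_names), n))
        mult[np.ix_(s_idx, phase == "S")] = 2.0 ** effect_log2
        mult[np.ix_(g_idx, phase == "G2M")] = 2.0 ** effect_log2
        return mult, phase

    return _simulate_engine(
        config,
        reserved_names=list(s_genes) + list(g2m_genes),
        cell_multiplier_fn=add_cycle,
    )


def simulate_cohort(
    n_tumors: int,
    signature: GeneSignature,
    pos_fraction: float,
    z_shift: float,
    hazard_ratio: float,
    censor_rate: float = 0.2,
    seed: int = 0,
    n_background_genes: int = 200,
    gene_universe=None,
    grade_odds: float = 1.0,
    subtype_odds: float = 1.0,
    os_median_months: float = 120.0,
    rfs_median_months: float = 80.0,
):
    """Simulate a bulk tumor cohort with a signature-positive subgroup.

    Expression is standard normal per gene (already on the z scale);
    positive tumors have every signature gene shifted up by ``z_shift``
    standard deviations.  Survival times are exponential, with the event
    rate multiplied by ``hazard_ratio`` in positives, under independent
    exponential censoring calibrated so the baseline group is censored with
    probability ``censor_rate``.  Grade 3 and the Luminal B subtype are
    enriched in positives by the given odds multipliers.

    Returns ``(CohortTable, truth)`` where truth is a boolean Series of the
    planted positive labels.
    """
    from .cohort import CohortTable

    if not (0 <= pos_fraction < 1):
        raise ValueError("pos_fraction must be in [0, 1)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    if gene_universe is not None:
        missing = [g for g in signature.genes if g not in set(gene_universe)]
        if missing:
            raise ValueError(f"signature genes absent from gene universe: {missing[:5]}")
        genes = list(gene_universe)
    else:
        genes = list(signature.genes) + [
            f"BG{i + 1:04d}" for i in range(n_background_genes)
        ]

    root = np.random.SeedSequence(seed)
    rng_expr, rng_label, rng_surv, rng_clin = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    tumors = [f"TUMOR{i + 1:04d}" for i in range(n_tumors)]
    positive = rng_label.random(n_tumors) < pos_fraction

    expr = rng_expr.standard_normal((len(genes), n_tumors))
    sig_rows = [i for i, g in enumerate(genes) if g in set(signature.genes)]
    expr[np.ix_(sig_rows, np.flatnonzero(positive))] += z_shift

    def survival(median):
        lam = math.log(2.0) / median
        rate = np.where(positive, lam * hazard_ratio, lam)
        t_event = rng_surv.exponential(1.0 / rate)
        if censor_rate > 0:
            c_rate = lam * censor_rate / (1.0 - censor_rate)
            t_cens = rng_surv.exponential(1.0 / c_rate, size=n_tumors)
        else:
            t_cens = np.full(n_tumors, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    os_t, os_e = survival(os_median_months)
    rfs_t, rfs_e = survival(rfs_median_months)

    def categorical(levels, base_p, enriched_level, odds):
        base_p = np.asarray(base_p, dtype=float)
        p_pos = base_p.copy()
        i = levels.index(enriched_level)
        p_pos[i] *= odds
        p_pos /= p_pos.sum()
        out = np.empty(n_tumors, dtype=object)
        for t in range(n_tumors):
            p = p_pos if positive[t] else base_p
            out[t] = levels[rng_clin.choice(len(levels), p=p)]
        return out

    grade = categorical(["1", "2", "3"], [0.2, 0.5, 0.3], "3", grade_odds)
    subtype = categorical(
        ["LumA", "LumB", "Her2", "Basal"], [0.5, 0.3, 0.1, 0.1], "LumB", subtype_odds
    )

    clinical = pd.DataFrame(
        {
            "grade": grade,
            "subtype": subtype,
            "rfs_months": rfs_t,
            "rfs_event": rfs_e,
            "os_months": os_t,
            "os_event": os_e,
        },
        index=pd.Index(tumors, name="tumor"),
    )
    expression = pd.DataFrame(expr, index=genes, columns=tumors)
    truth = pd.Series(positive, index=tumors, name="positive")
    return CohortTable(expression=expression, clinical=clinical), truth


def simulate_limiting_dilution(
    frequency: float,
    doses,
    wells_per_dose: int = 6,
    seed: int = 0,
    group: str = "group",
) -> pd.DataFrame:
    """Simulate limiting-dilution outcomes under the single-hit model.

    Each well seeded with ``d`` cells responds independently with
    probability ``1 - exp(-frequency * d)``.
    """
    if not (0 <= frequency <= 1):
        raise ValueError("frequency must be in [0, 1]")
    doses = [int(d) for d in doses]
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive integers")
    if wells_per_dose <= 0:
        raise ValueError("wells_per_dose must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        p = -math.expm1(-frequency * d)
        rows.append(
            {
                "dose": d,
                "tested": wells_per_dose,
                "response": int(rng.binomial(wells_per_dose, p)),
                "group": group,
            }
        )
    return pd.DataFrame(rows)
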