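"""Synthetic study generator: toy genome, dual-state references, bulk mixtures.

The generator emulates the measurement design of a targeted bisulfite panel
on a colorectal-tumor cohort: ten cell-state classes (two stromal classes
plus four immune cell types in two compartments, tumor-infiltrating and
peripheral-blood-like), per-CpG beta profiles with planted class markers and
planted TIIC/PBMC state differences, Dirichlet bulk mixtures under linear
mixing, binomial read counts at negative-binomial coverage, and recurrence
labels driven by a logistic model of selected cell-state fractions plus
clinical covariates.

Everything downstream of this module is benchmarked against the ground
truth objects returned here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import BulkMethylome, ReferenceAtlas, cpg_id

DEFAULT_CLASS_LABELS = (
    "fibroblast",
    "epithelial",
    "TIIC-CD4T",
    "TIIC-CD8T",
    "TIIC-DC",
    "TIIC-macrophage",
    "PBMC-CD4T",
    "PBMC-CD8T",
    "PBMC-DC",
    "PBMC-monocyte",
)

# Matched immune cell types across the two compartments; macrophages pair
# with monocytes (the same lineage sorted from tumor vs blood).
MATCHED_IMMUNE_TYPES: dict[str, tuple[str, str]] = {
    "CD4T": ("TIIC-CD4T", "PBMC-CD4T"),
    "CD8T": ("TIIC-CD8T", "PBMC-CD8T"),
    "DC": ("TIIC-DC", "PBMC-DC"),
    "macrophage-monocyte": ("TIIC-macrophage", "PBMC-monocyte"),
}

# Dendritic-cell activation/maturation markers whose regulatory elements the
# interpretation stage interrogates (IL12 is a heterodimer, hence A and B).
DC_MARKER_GENES = (
    "HLA-DRA",
    "CCR7",
    "CD40",
    "CCL22",
    "IFNG",
    "IL12A",
    "IL12B",
    "CD86",
)

MIGRATION_TERM = "GO:TOY-MIGRATION"
DC_ACTIVATION_TERM = "GO:TOY-DC-ACTIVATION"
IMMUNE_TERMS = frozenset({MIGRATION_TERM, DC_ACTIVATION_TERM})


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the simulated conditions.

    Effect sizes are in beta units; ``dirichlet_alpha`` is the concentration
    vector over classes (epithelial-dominated tumors with minor immune
    fractions); ``label_coefficients`` are log-odds weights on true cell
    fractions, negative for the tumor-infiltrating CD8T/DC populations whose
    abundance marks non-recurring patients.
    """

    n_classes: int = 10
    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS
    n_cpgs: int = 1000
    n_marker_cpgs_per_class: int = 20
    delta_beta_marker: float = 0.4
    n_state_dmcs: int = 100
    delta_beta_state: float = 0.4
    n_replicates: int = 3
    replicate_sd: float = 0.02
    coverage_mean: float = 30.0
    coverage_dispersion: float = 0.3
    dirichlet_alpha: tuple[float, ...] = (3.0, 6.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    # zero-sum coefficient structure (Sum over classes of coef*alpha = 0):
    # under the Dirichlet every fraction outside the informative set is then
    # marginally uncorrelated with the composition signal, so the label is
    # carried by the named cell states and not by compositional closure
    label_coefficients: dict[str, float] = field(
        default_factory=lambda: {"TIIC-CD8T": -10.0, "TIIC-DC": -12.0, "PBMC-DC": 22.0}
    )
    label_intercept: float = -0.7
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {"tnm_stage": 0.4, "metastasis": 0.8, "msi": -0.6}
    )
    tnm_probs: tuple[float, ...] = (0.2, 0.3, 0.35, 0.15)
    metastasis_rate: float = 0.25
    msi_rate: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must equal n_classes")
        if len(self.dirichlet_alpha) != self.n_classes:
            raise ValueError("dirichlet_alpha length must equal n_classes")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha must be strictly positive")
        for name, v in (
            ("delta_beta_marker", self.delta_beta_marker),
            ("delta_beta_state", self.delta_beta_state),
        ):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        unknown = set(self.label_coefficients) - set(self.class_labels)
        if unknown:
            raise ValueError(f"label_coefficients for unknown classes: {sorted(unknown)}")


@dataclass
class ToyGenome:
    """Coordinate frame of the synthetic panel.

    Regulatory-element intervals are 0-based half-open; CpG positions are
    0-based and strictly increasing within each chromosome.  The planted
    index bookkeeping (which CpGs carry class markers or state differences)
    travels with the genome so reference generation is reproducible.
    """

    chrom_sizes: dict[str, int]
    cpg_chroms: np.ndarray  # object array of chromosome names, len n_cpgs
    cpg_positions: np.ndarray  # int positions, len n_cpgs
    re_intervals: list[tuple[str, int, int, str]]
    re_targets: dict[str, str]
    gene_sets: dict[str, set[str]]
    marker_idx: dict[str, np.ndarray]
    state_dmc_idx: dict[str, np.ndarray]

    @property
    def cpg_ids(self) -> pd.Index:
        return pd.Index(
            [cpg_id(c, int(p)) for c, p in zip(self.cpg_chroms, self.cpg_positions)]
        )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def all_state_dmc_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.state_dmc_idx.values())))

    def all_marker_indices(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.marker_idx.values())))


@dataclass
class GroundTruth:
    """What the generator actually planted, for benchmarking recovery."""

    planted_class_markers: dict[str, set[str]]
    planted_state_dmcs: dict[str, set[str]]
    class_profiles: pd.DataFrame | None = None  # CpG x class true betas
    true_proportions: pd.DataFrame | None = None  # sample x class
    label_model: dict | None = None
    recurrence_probability: pd.Series | None = None
    state_dmc_direction: pd.Series | None = None  # +1 hyper-in-TIIC, -1 hypo


def _immune_partitions(config: SimulationConfig) -> dict[str, int]:
    """Split the planted state DMCs across matched immune types."""
    types = list(MATCHED_IMMUNE_TYPES)
    base, extra = divmod(config.n_state_dmcs, len(types))
    return {t: base + (1 if i < extra else 0) for i, t in enumerate(types)}


def generate_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Lay out CpGs, regulatory elements and gene sets on a toy genome.

    Planted state DMCs each receive a nearby regulatory element (within the
    1,250 bp mapping window) targeting either a dendritic-cell marker gene
    (the DC partition) or a migration-set gene; ~30% of non-planted CpGs get
    a nearby background-gene RE, the rest lie beyond the window from every
    RE, so RE mapping and enrichment are testable against the plant.
    """
    needed = config.n_classes * config.n_marker_cpgs_per_class + config.n_state_dmcs
    if config.n_cpgs < needed:
        raise ValueError(
            f"n_cpgs={config.n_cpgs} too small: need at least {needed} "
            f"({config.n_classes} classes x {config.n_marker_cpgs_per_class} markers "
            f"+ {config.n_state_dmcs} state DMCs); deficit {needed - config.n_cpgs}"
        )
    rng = np.random.default_rng(config.seed)

    n1 = int(round(config.n_cpgs * 0.6))
    counts = {"chr1": n1, "chr2": config.n_cpgs - n1}
    chroms: list[str] = []
    positions: list[int] = []
    chrom_sizes: dict[str, int] = {}
    for chrom, n in counts.items():
        gaps = 3000 + rng.integers(0, 400, size=n)
        pos = 10_000 + np.cumsum(gaps)
        chroms.extend([chrom] * n)
        positions.extend(int(p) for p in pos)
        chrom_sizes[chrom] = int(pos[-1] + 10_000) if n else 20_000
    cpg_chroms = np.array(chroms, dtype=object)
    cpg_positions = np.array(positions, dtype=np.int64)

    # planted indices: class markers then state DMCs, disjoint
    order = rng.permutation(config.n_cpgs)
    cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    for label in config.class_labels:
        marker_idx[label] = np.sort(order[cursor : cursor + config.n_marker_cpgs_per_class])
        cursor += config.n_marker_cpgs_per_class
    state_dmc_idx: dict[str, np.ndarray] = {}
    for t, n in _immune_partitions(config).items():
        state_dmc_idx[t] = np.sort(order[cursor : cursor + n])
        cursor += n

    re_intervals: list[tuple[str, int, int, str]] = []
    re_targets: dict[str, str] = {}
    re_counter = 0

    def add_re(chrom: str, start: int, gene: str, width: int = 200) -> None:
        nonlocal re_counter
        rid = f"RE{re_counter:05d}"
        re_counter += 1
        re_intervals.append((chrom, int(start), int(start + width), rid))
        re_targets[rid] = gene

    # REs near planted state DMCs
    mig_genes = [f"MIG{i:03d}" for i in range(75)]
    mig_cursor = 0
    for t, idx in state_dmc_idx.items():
        for j, i in enumerate(idx):
            offset = int(rng.integers(300, 800))
            side = 1 if rng.random() < 0.5 else -1
            start = cpg_positions[i] + side * offset - (200 if side < 0 else 0)
            if t == "DC":
                gene = DC_MARKER_GENES[j % len(DC_MARKER_GENES)]
            else:
                gene = mig_genes[mig_cursor % len(mig_genes)]
                mig_cursor += 1
            add_re(str(cpg_chroms[i]), start, gene)

    # background REs near ~30% of non-planted CpGs
    planted = np.concatenate(
        [v for v in marker_idx.values()] + [v for v in state_dmc_idx.values()]
    )
    non_planted = np.setdiff1d(np.arange(config.n_cpgs), planted)
    bg_genes = [f"BG{i:03d}" for i in range(60)]
    n_near = int(round(0.3 * len(non_planted)))
    near = rng.choice(non_planted, size=n_near, replace=False)
    for k, i in enumerate(np.sort(near)):
        offset = int(rng.integers(300, 800))
        add_re(str(cpg_chroms[i]), cpg_positions[i] + offset, bg_genes[k % len(bg_genes)])

    # distant REs in inter-CpG gaps (beyond the 1,250 bp window of any CpG)
    far = rng.choice(non_planted[:-1], size=min(40, len(non_planted) - 1), replace=False)
    for k, i in enumerate(np.sort(far)):
        add_re(str(cpg_chroms[i]), cpg_positions[i] + 1400, bg_genes[(k + 30) % len(bg_genes)], width=100)

    gene_sets = {
        MIGRATION_TERM: set(mig_genes),
        DC_ACTIVATION_TERM: set(DC_MARKER_GENES),
        "GO:TOY-HOUSEKEEPING": set(bg_genes[:30]),
        "GO:TOY-METABOLISM": set(bg_genes[30:]),
    }

    return ToyGenome(
        chrom_sizes=chrom_sizes,
        cpg_chroms=cpg_chroms,
        cpg_positions=cpg_positions,
        re_intervals=re_intervals,
        re_targets=re_targets,
        gene_sets=gene_sets,
        marker_idx=marker_idx,
        state_dmc_idx=state_dmc_idx,
    )


def _bimodal_background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Background betas concentrated near 0 and 1, as in real methylomes."""
    low = rng.beta(0.5, 8.0, size=n)
    high = rng.beta(8.0, 0.5, size=n)
    return np.where(rng.random(n) < 0.5, low, high)


def _class_profile_matrix(
    genome: ToyGenome, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True per-class beta profiles with planted effects.

    Class markers shift one class away from the shared background by
    ``delta_beta_marker``.  State DMCs are modeled as a pan-immune
    compartment shift: every TIIC class moves by +/- ``delta_beta_state``
    relative to the PBMC classes, stromal classes sit at the half-shift.
    DC-partition DMCs are forced hypomethylated in TIIC (the activated-DC
    demethylation signal); other partitions draw a random direction.
    Returns (profiles, direction) where direction is +/-1 at state DMCs.
    """
    labels = list(config.class_labels)
    n_cpgs = genome.n_cpgs
    base = _bimodal_background(rng, n_cpgs)
    profiles = np.tile(base[:, None], (1, len(labels)))

    for label in labels:
        idx = genome.marker_idx[label]
        k = labels.index(label)
        b = base[idx]
        shift = np.where(b < 0.5, config.delta_beta_marker, -config.delta_beta_marker)
        profiles[idx, k] = b + shift

    tiic_cols = [labels.index(l) for l in labels if l.startswith("TIIC-")]
    pbmc_cols = [labels.index(l) for l in labels if l.startswith("PBMC-")]
    stromal_cols = [labels.index(l) for l in labels if not (l.startswith("TIIC-") or l.startswith("PBMC-"))]

    direction = np.zeros(n_cpgs)
    for t, idx in genome.state_dmc_idx.items():
        if t == "DC":
            d = -np.ones(len(idx))
        else:
            d = rng.choice([-1.0, 1.0], size=len(idx))
        direction[idx] = d
        # re-draw the base so the full shift stays inside [0, 1]
        lo = rng.uniform(0.05, 0.40, size=len(idx))
        hi = rng.uniform(0.60, 0.95, size=len(idx))
        b = np.where(d > 0, lo, hi)
        profiles[idx, :] = b[:, None]
        for c in tiic_cols:
            profiles[idx, c] = b + d * config.delta_beta_state
        for c in stromal_cols:
            profiles[idx, c] = b + d * config.delta_beta_state / 2.0
        # PBMC columns stay at b
    return np.clip(profiles, 0.0, 1.0), direction


def _nb_coverage(
    rng: np.random.Generator, mean: float, dispersion: float, shape
) -> np.ndarray:
    """Negative-binomial coverage with var = mean + dispersion * mean^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    cov = rng.negative_binomial(r, p, size=shape)
    return np.maximum(cov, 1)


def generate_reference_profiles(
    genome: ToyGenome, config: SimulationConfig
) -> tuple[ReferenceAtlas, GroundTruth]:
    """Sorted-cell reference methylomes: replicate betas and read counts."""
    rng = np.random.default_rng([config.seed, 1])
    labels = list(config.class_labels)
    profiles, direction = _class_profile_matrix(genome, config, rng)
    cpg_ids = genome.cpg_ids

    cols: list[str] = []
    class_of: list[str] = []
    betas = np.empty((genome.n_cpgs, len(labels) * config.n_replicates))
    j = 0
    for k, label in enumerate(labels):
        for r in range(config.n_replicates):
            noise = rng.normal(0.0, config.replicate_sd, size=genome.n_cpgs)
            betas[:, j] = np.clip(profiles[:, k] + noise, 0.0, 1.0)
            cols.append(f"{label}.rep{r + 1}")
            class_of.append(label)
            j += 1

    coverage = _nb_coverage(
        rng, config.coverage_mean, config.coverage_dispersion, betas.shape
    )
    meth = rng.binomial(coverage, betas)

    sample_ids = pd.Index(cols)
    atlas = ReferenceAtlas(
        cpg_ids=cpg_ids,
        sample_ids=sample_ids,
        betas=pd.DataFrame(betas, index=cpg_ids, columns=sample_ids),
        methylated=pd.DataFrame(meth, index=cpg_ids, columns=sample_ids),
        total=pd.DataFrame(coverage, index=cpg_ids, columns=sample_ids),
        class_labels=pd.Series(class_of, index=sample_ids),
    )
    truth = GroundTruth(
        planted_class_markers={
            l: set(cpg_ids[genome.marker_idx[l]]) for l in labels
        },
        planted_state_dmcs={
            t: set(cpg_ids[idx]) for t, idx in genome.state_dmc_idx.items()
        },
        class_profiles=pd.DataFrame(profiles, index=cpg_ids, columns=labels),
        state_dmc_direction=pd.Series(direction, index=cpg_ids),
    )
    return atlas, truth


def generate_bulk_cohort(
    atlas: ReferenceAtlas,
    genome: ToyGenome,
    config: SimulationConfig,
    n_samples: int,
    seed: int | None = None,
    beta_mode: bool = False,
):
    """Bulk mixtures with known proportions, counts, and clinical labels.

    Bulk beta is the proportion-weighted sum of per-class mean reference
    profiles plus Gaussian noise, clipped to [0, 1].  With ``beta_mode``
    and ``noise_sd == 0`` the output betas equal the linear mixture exactly
    (no read-count resampling).  Returns (bulk, clinical, truth).
    """
    from .recurrence import ClinicalTable  # local import to avoid a cycle

    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be strictly positive")
    rng = np.random.default_rng([config.seed if seed is None else seed, 2])
    labels = list(config.class_labels)

    # mixing basis: per-class mean of the reference replicates
    basis = np.column_stack(
        [atlas.betas[atlas.samples_of_class(l)].mean(axis=1).to_numpy() for l in labels]
    )

    W = rng.dirichlet(alpha, size=n_samples)  # sample x class
    bulk = basis @ W.T
    if config.noise_sd > 0:
        bulk = bulk + rng.normal(0.0, config.noise_sd, size=bulk.shape)
    bulk = np.clip(bulk, 0.0, 1.0)

    sample_ids = pd.Index([f"patient{i + 1:03d}" for i in range(n_samples)])
    meth = total = None
    if not beta_mode:
        total_arr = _nb_coverage(
            rng, config.coverage_mean, config.coverage_dispersion, bulk.shape
        )
        meth_arr = rng.binomial(total_arr, bulk)
        meth = pd.DataFrame(meth_arr, index=atlas.cpg_ids, columns=sample_ids)
        total = pd.DataFrame(total_arr, index=atlas.cpg_ids, columns=sample_ids)

    bulk_obj = BulkMethylome(
        cpg_ids=atlas.cpg_ids,
        sample_ids=sample_ids,
        betas=pd.DataFrame(bulk, index=atlas.cpg_ids, columns=sample_ids),
        methylated=meth,
        total=total,
    )

    # clinical covariates
    tnm = rng.choice(np.arange(1, 5), size=n_samples, p=np.asarray(config.tnm_probs))
    metastasis = (rng.random(n_samples) < config.metastasis_rate).astype(int)
    msi = (rng.random(n_samples) < config.msi_rate).astype(int)
    side = np.where(rng.random(n_samples) < 0.5, "left", "right")
    organ = np.where(rng.random(n_samples) < 0.7, "colon", "rectum")
    adjuvant = (rng.random(n_samples) < 0.5).astype(int)

    coef = np.array([config.label_coefficients.get(l, 0.0) for l in labels])
    logit = (
        config.label_intercept
        + W @ coef
        + config.clinical_effects.get("tnm_stage", 0.0) * (tnm - 2)
        + config.clinical_effects.get("metastasis", 0.0) * metastasis
        + config.clinical_effects.get("msi", 0.0) * msi
    )
    p_rec = 1.0 / (1.0 + np.exp(-logit))
    recurrence = (rng.random(n_samples) < p_rec).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "recurrence": recurrence,
                "tnm_stage": tnm,
                "metastasis": metastasis,
                "msi": msi,
                "tumor_location_side": side,
                "tumor_location_organ": organ,
                "adjuvant_therapy": adjuvant,
            },
            index=sample_ids,
        )
    )

    truth = GroundTruth(
        planted_class_markers={
            l: set(atlas.cpg_ids[genome.marker_idx[l]]) for l in labels
        },
        planted_state_dmcs={
            t: set(atlas.cpg_ids[idx]) for t, idx in genome.state_dmc_idx.items()
        },
        true_proportions=pd.DataFrame(W, index=sample_ids, columns=labels),
        label_model={
            "coefficients": dict(config.label_coefficients),
            "intercept": config.label_intercept,
            "clinical_effects": dict(config.clinical_effects),
        },
        recurrence_probability=pd.Series(p_rec, index=sample_ids),
    )
    return bulk_obj, clinical, truth


def simulate_study(
    config: SimulationConfig | None = None, n_samples: int = 114, seed: int | None = None
):
    """One-call convenience: genome, references, and a bulk cohort."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
        config.label_coefficients = dict(config.label_coefficients)
    genome = generate_toy_genome(config)
    atlas, ref_truth = generate_reference_profiles(genome, config)
    bulk, clinical, truth = generate_bulk_cohort(atlas, genome, config, n_samples)
    truth.class_profiles = ref_truth.class_profiles
    truth.state_dmc_direction = ref_truth.state_dmc_direction
    return genome, atlas, bulk, clinical, truth
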