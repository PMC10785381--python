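"""Synthetic semi-field experiments with the statistical structure the
analysis assumes.

The generator emulates the study conditions: around 70 inbred lines
genotyped at a few thousand biallelic SNPs (dosages mostly 0/2, giving an
average genomic-relationship diagonal near 1.86), randomised onto 2 beds x
2 half-bed units x 150 rows with wet/dry half-row observations, and three
minirhizotron imaging time points with images every 5 cm of soil depth.
Above-ground phenotypes are drawn from the above-ground model equation with
variance components defaulting to the magnitudes estimated in the study;
root phenotypes follow the root-model equation at the tube x time-point
level, and image-level root lengths are allocated over the depth grid by a
unimodal (Gaussian) depth profile that deepens across time points, so that
summing the images recovers the latent total root length exactly.

All randomness flows from one seed through named substreams, so adding a
draw in one component does not shift any other component's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
from scipy import linalg

from .exceptions import ConfigurationError
from .genomics import GenotypeMatrix, Grm, compute_grm, impute_missing
from .layout import Layout, SpatialStructure, build_layout, build_s_euc, build_s_knn

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedExperiment",
    "simulate_genotypes",
    "assign_lines",
    "simulate_above_ground",
    "simulate_root_images",
    "simulate_experiment",
]

_STREAMS = {
    "genotypes": 11,
    "missing": 12,
    "lines": 21,
    "above": 31,
    "roots": 41,
}

# Variance-component magnitudes of the study's above-ground estimates
# (neighbour and interaction variances effectively zero).
DEFAULT_VCS_ABOVE: dict[str, dict[str, float]] = {
    "GY": {"g": 0.23, "l": 0.11, "ng": 0.0, "nl": 0.0, "r": 0.13,
           "tg": 0.01, "tl": 0.01, "s1": 0.12, "s2": 0.06, "residual": 0.48},
    "GPC": {"g": 0.09, "l": 0.01, "ng": 0.0, "nl": 0.0, "r": 0.03,
            "tg": 0.0035, "tl": 0.0018, "s1": 0.26, "s2": 0.16, "residual": 0.04},
    "TKW": {"g": 8.97, "l": 4.49, "ng": 0.0, "nl": 0.0, "r": 0.55,
            "tg": 0.01, "tl": 0.0, "s1": 0.44, "s2": 1.41, "residual": 2.62},
}

# Treatment means (wet, dry) per trait, matching the study's fixed-effect
# estimates.
DEFAULT_FIXED_MEANS: dict[str, tuple[float, float]] = {
    "GY": (7.20, 6.91),
    "GPC": (9.30, 9.59),
    "TKW": (53.42, 52.40),
}

# Root-trait variance components at the study's total-root-length scale.
DEFAULT_VCS_ROOT: dict[str, float] = {
    "g": 10.13, "l": 1e-6, "r": 127.82,
    "s1": 61.89, "s2": 88.45, "s3": 232.72, "residual": 50.0,
}

# Mean total root length per time point (cm), deepening root systems.
DEFAULT_ROOT_MEANS = (20.0, 34.0, 46.0)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; the seed is mandatory."""

    seed: int
    n_lines: int = 70
    n_snps: int = 3000
    n_founders: int = 12
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbreeding: float = 0.95
    missing_rate: float = 0.0
    beds: int = 2
    units_per_bed: int = 2
    rows_per_unit: int = 150
    row_spacing: float = 0.25
    k_neighbors: int = 5
    d_max: float = 2.75
    spatial_kind: str = "knn"
    traits: tuple[str, ...] = ("GY", "GPC", "TKW")
    vcs_above: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VCS_ABOVE.items()})
    fixed_means: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_MEANS))
    unit_bed_sd: float = 0.02  # fixed unit-bed offsets, as a fraction of the trait mean
    n_time_points: int = 3
    vcs_root: dict = field(default_factory=lambda: dict(DEFAULT_VCS_ROOT))
    root_means: tuple[float, ...] = DEFAULT_ROOT_MEANS
    depth_grid: tuple[float, float, float] = (40.0, 270.0, 5.0)
    depth_profile_mean: tuple[float, ...] = (80.0, 110.0, 140.0)
    depth_profile_sd: tuple[float, ...] = (30.0, 35.0, 40.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for reproducibility")
        for trait, vcs in self.vcs_above.items():
            if any(v < 0 for v in vcs.values()):
                raise ConfigurationError(f"negative variance for {trait}")
        if any(v < 0 for v in self.vcs_root.values()):
            raise ConfigurationError("negative root variance")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Generating values stored for parameter-recovery checks."""

    seed: int
    vcs: dict
    breeding_values: pd.DataFrame  # line x trait
    spatial_fields: dict  # name -> pd.Series over row ids
    latent_roots: pd.DataFrame | None = None


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Biallelic dosages for inbred lines from a structured breeding population.

    Per SNP an allele frequency is drawn uniformly from ``maf_range`` and a
    small pool of fully inbred founders is sampled at those frequencies.
    Each line descends from a random pair of founders, inheriting either
    parent's allele independently per SNP (a doubled-haploid-like derivative
    without linkage), with residual heterozygosity ``1 - inbreeding``.  The
    founder structure creates the family relatedness (full and half sibs)
    genomic prediction relies on, and the default settings give an average
    relationship diagonal near 1.86.  Optional missingness supports QC
    testing.
    """
    rng = config.rng("genotypes")
    L, S = config.n_lines, config.n_snps
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=S)
    founders = 2.0 * (rng.random((config.n_founders, S)) < p)
    parents = rng.integers(0, config.n_founders, size=(L, 2))
    pick_a = rng.random((L, S)) < 0.5
    dosage = np.where(pick_a, founders[parents[:, 0]], founders[parents[:, 1]])
    het = rng.random((L, S)) < (1.0 - config.inbreeding)
    dosage = np.where(het, 1.0, dosage)
    if config.missing_rate > 0:
        miss = config.rng("missing").random((L, S)) < config.missing_rate
        dosage = np.where(miss, np.nan, dosage)
    lines = [f"L{i + 1:03d}" for i in range(L)]
    snps = [f"S{j + 1:05d}" for j in range(S)]
    return GenotypeMatrix(pd.DataFrame(dosage, index=lines, columns=snps))


def assign_lines(config: SimulationConfig, layout: Layout, line_ids) -> Layout:
    """Randomise lines onto the real rows of every half-bed unit."""
    rng = config.rng("lines")
    line_ids = list(line_ids)
    mapping: dict[tuple[int, int, int], str] = {}
    for bed in range(1, config.beds + 1):
        for unit in range(1, config.units_per_bed + 1):
            reps = int(np.ceil(config.rows_per_unit / len(line_ids)))
            pool = np.array(line_ids * reps)[: config.rows_per_unit]
            rng.shuffle(pool)
            for idx in range(config.rows_per_unit):
                mapping[(bed, unit, idx)] = str(pool[idx])
    return layout.with_lines(mapping)


def _chol_psd(K: np.ndarray) -> np.ndarray:
    jitter = 1e-8 * float(np.mean(np.diag(K)))
    return np.linalg.cholesky(K + jitter * np.eye(K.shape[0]))


def _structure(config: SimulationConfig, layout: Layout) -> SpatialStructure:
    if config.spatial_kind == "knn":
        return build_s_knn(layout, k=config.k_neighbors)
    if config.spatial_kind == "euc":
        return build_s_euc(layout, d_max=config.d_max)
    raise ConfigurationError(f"unknown spatial kind {config.spatial_kind!r}")


def simulate_above_ground(
    config: SimulationConfig,
    geno: GenotypeMatrix,
    layout: Layout,
    grm: Grm | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Half-row records for the above-ground traits drawn from the model equation.

    One record per real row and treatment; every random term is drawn from
    its stated normal distribution at the configured variance components.
    Neighbour effects load the left and right flanking line of each row.
    The returned table also carries sample weight and seed count consistent
    with the generated kernel weight, and the derived nitrogen-removal
    column.
    """
    if grm is None:
        grm = compute_grm(impute_missing(geno))
    lines = grm.line_ids
    line_pos = {l: i for i, l in enumerate(lines)}
    G = grm.values
    Lg = _chol_psd(G)

    structure = _structure(config, layout)
    Ls = _chol_psd(structure.S)
    row_index = {rid: i for i, rid in enumerate(structure.row_ids)}

    real = [r for r in layout.real_rows]
    if any(r.line is None for r in real):
        raise ConfigurationError("layout rows carry no lines; call assign_lines first")
    line_of = {(r.bed, r.unit, r.index): r.line for r in real}

    rng = config.rng("above")
    records: dict[str, list] = {c: [] for c in ("bed", "unit", "row", "treatment", "line")}
    for r in real:
        for trt in ("wet", "dry"):
            records["bed"].append(r.bed)
            records["unit"].append(r.unit)
            records["row"].append(r.index)
            records["treatment"].append(trt)
            records["line"].append(r.line)
    df = pd.DataFrame(records)
    n = len(df)
    wet = (df["treatment"] == "wet").to_numpy()
    obs_line = df["line"].map(line_pos).to_numpy()
    obs_row = np.array(
        [row_index[f"b{b}u{u}r{i}"] for b, u, i in zip(df["bed"], df["unit"], df["row"])]
    )

    # unit-bed fixed offsets shared across traits' structure, drawn per trait
    bv = {}
    fields = {}
    for trait in config.traits:
        vcs = config.vcs_above[trait]
        mean_wet, mean_dry = config.fixed_means[trait]
        sd = np.sqrt
        g = Lg @ rng.standard_normal(len(lines)) * sd(vcs["g"])
        l = rng.standard_normal(len(lines)) * sd(vcs["l"])
        n_g = Lg @ rng.standard_normal(len(lines)) * sd(vcs["ng"])
        n_l = rng.standard_normal(len(lines)) * sd(vcs["nl"])
        r_eff = rng.standard_normal(structure.n) * sd(vcs["r"])
        tg = {t: Lg @ rng.standard_normal(len(lines)) * sd(vcs["tg"]) for t in ("wet", "dry")}
        tl = {t: rng.standard_normal(len(lines)) * sd(vcs["tl"]) for t in ("wet", "dry")}
        s1 = Ls @ rng.standard_normal(structure.n) * sd(vcs["s1"])
        s2 = Ls @ rng.standard_normal(structure.n) * sd(vcs["s2"])
        e = rng.standard_normal(n) * sd(vcs["residual"])
        base_mean = (mean_wet + mean_dry) / 2.0
        offsets = rng.standard_normal(config.beds * config.units_per_bed)
        offsets *= config.unit_bed_sd * base_mean
        ub_index = (
            (df["bed"].to_numpy() - 1) * config.units_per_bed + (df["unit"].to_numpy() - 1)
        )

        nb = np.zeros(n)
        for i, (b, u, ridx) in enumerate(zip(df["bed"], df["unit"], df["row"])):
            for step in (-1, 1):
                key = (b, u, ridx + step)
                if key in line_of:
                    j = line_pos[line_of[key]]
                    nb[i] += n_g[j] + n_l[j]

        y = (
            np.where(wet, mean_wet, mean_dry)
            + offsets[ub_index]
            + g[obs_line]
            + l[obs_line]
            + nb
            + r_eff[obs_row]
            + np.where(wet, [tg["wet"][j] for j in obs_line], [tg["dry"][j] for j in obs_line])
            + np.where(wet, [tl["wet"][j] for j in obs_line], [tl["dry"][j] for j in obs_line])
            + np.where(wet, s1[obs_row], s2[obs_row])
            + e
        )
        df[trait] = y
        bv[trait] = pd.Series(g, index=lines)
        fields[f"{trait}_s1"] = pd.Series(s1, index=structure.row_ids)
        fields[f"{trait}_s2"] = pd.Series(s2, index=structure.row_ids)

    if "GY" in df.columns and "GPC" in df.columns:
        df["GNR"] = df["GY"].clip(lower=0) * df["GPC"].clip(lower=0) / 6.25 * 10.0
    if "TKW" in df.columns:
        df["seed_count"] = 500
        df["sample_weight"] = df["TKW"] * df["seed_count"] / 1000.0

    truth = SyntheticTruth(
        seed=config.seed,
        vcs={t: dict(config.vcs_above[t]) for t in config.traits},
        breeding_values=pd.DataFrame(bv),
        spatial_fields=fields,
    )
    return df, truth


def simulate_root_images(
    config: SimulationConfig,
    geno: GenotypeMatrix,
    layout: Layout,
    grm: Grm | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Minirhizotron image records for total root length.

    Unit 1 of every bed is minirhizotron-equipped, one tube per row.  The
    latent tube x time-point total root length follows the root model
    equation; image lengths on the 5 cm depth grid are a Gaussian depth
    profile (deepening over time points) scaled to the latent total, so the
    images sum back to it exactly.  Negative latent values truncate to zero
    (tubes with no visible roots).
    """
    if grm is None:
        grm = compute_grm(impute_missing(geno))
    lines = grm.line_ids
    line_pos = {l: i for i, l in enumerate(lines)}
    Lg = _chol_psd(grm.values)

    structure = _structure(config, layout)
    Ls = _chol_psd(structure.S)
    row_index = {rid: i for i, rid in enumerate(structure.row_ids)}

    mr_unit = 1
    tubes = [r for r in layout.real_rows if r.unit == mr_unit]
    if any(r.line is None for r in tubes):
        raise ConfigurationError("layout rows carry no lines; call assign_lines first")

    rng = config.rng("roots")
    vcs = config.vcs_root
    sd = np.sqrt
    g = Lg @ rng.standard_normal(len(lines)) * sd(vcs["g"])
    l = rng.standard_normal(len(lines)) * sd(vcs["l"])
    r_eff = rng.standard_normal(structure.n) * sd(vcs["r"])
    s_fields = {
        k: Ls @ rng.standard_normal(structure.n) * sd(vcs[f"s{k}"])
        for k in range(1, config.n_time_points + 1)
    }

    d_lo, d_hi, d_step = config.depth_grid
    depths = np.arange(d_lo, d_hi + 0.5 * d_step, d_step)

    latent_rows = []
    image_rows = []
    for tube in tubes:
        rid = tube.row_id
        si = row_index[rid]
        j = line_pos[tube.line]
        for k in range(1, config.n_time_points + 1):
            e = rng.standard_normal() * sd(vcs["residual"])
            latent = (
                config.root_means[k - 1] + g[j] + l[j] + r_eff[si] + s_fields[k][si] + e
            )
            trl = max(latent, 0.0)
            latent_rows.append(
                {"bed": tube.bed, "unit": tube.unit, "tube": tube.index,
                 "time": k, "line": tube.line, "latent_trl": trl}
            )
            mu = config.depth_profile_mean[k - 1]
            sig = config.depth_profile_sd[k - 1]
            w = np.exp(-0.5 * ((depths - mu) / sig) ** 2)
            w /= w.sum()
            lengths = trl * w
            for d, ln in zip(depths, lengths):
                image_rows.append(
                    {"bed": tube.bed, "unit": tube.unit, "tube": tube.index,
                     "camera": tube.bed, "time": k, "line": tube.line,
                     "depth": d, "length": ln}
                )
    images = pd.DataFrame(image_rows)
    latent = pd.DataFrame(latent_rows)
    truth = SyntheticTruth(
        seed=config.seed,
        vcs=dict(vcs),
        breeding_values=pd.DataFrame({"TRL": pd.Series(g, index=lines)}),
        spatial_fields={f"s{k}": pd.Series(v, index=structure.row_ids) for k, v in s_fields.items()},
        latent_roots=latent,
    )
    return images, truth


@dataclass
class SimulatedExperiment:
    """A full synthetic experiment bundle."""

    config: SimulationConfig
    geno: GenotypeMatrix
    grm: Grm
    layout: Layout
    above: pd.DataFrame
    above_truth: SyntheticTruth
    root_images: pd.DataFrame
    root_truth: SyntheticTruth


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate genotypes, layout, above-ground records and root images."""
    geno = simulate_genotypes(config)
    grm = compute_grm(impute_missing(geno))
    layout = build_layout(
        beds=config.beds,
        units_per_bed=config.units_per_bed,
        rows_per_unit=config.rows_per_unit,
        row_spacing=config.row_spacing,
        k_neighbors=config.k_neighbors,
        d_max=config.d_max,
    )
    layout = assign_lines(config, layout, geno.line_ids)
    above, above_truth = simulate_above_ground(config, geno, layout, grm=grm)
    images, root_truth = simulate_root_images(config, geno, layout, grm=grm)
    return SimulatedExperiment(
        config=config,
        geno=geno,
        grm=grm,
        layout=layout,
        above=above,
        above_truth=above_truth,
        root_images=images,
        root_truth=root_truth,
    )
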