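"""Synthetic inputs with planted statistical structure for every stage.

Each generator is deterministic given (spec, seed) and returns a
machine-readable truth record holding every planted parameter, so that
downstream recovery tests can compare estimates against ground truth while
consuming only the generated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import BrainVolume, derive_rng
from .exceptions import SimSpecError
from .lc_signal import neighbor_offsets

__all__ = [
    "CohortSimSpec",
    "TangleSimSpec",
    "ExpressionSimSpec",
    "gen_lc_slab",
    "gen_cohort",
    "gen_tangles",
    "gen_expression",
    "make_blob",
]


def make_blob(shape: tuple[int, int, int], center: tuple[int, int, int],
              radius: int = 2) -> list[tuple[int, int, int]]:
    """Connected ball of voxels around ``center``, clipped to the grid."""
    out = []
    c = np.asarray(center)
    for idx in np.ndindex(*[2 * radius + 1] * 3):
        p = c + np.asarray(idx) - radius
        if np.any(p < 0) or np.any(p >= np.asarray(shape)):
            continue
        if np.sum((p - c) ** 2) <= radius * radius:
            out.append(tuple(int(v) for v in p))
    return out


def _is_connected(voxels: Sequence[tuple[int, int, int]]) -> bool:
    vox = {tuple(v) for v in voxels}
    if not vox:
        return False
    offsets = neighbor_offsets("3d")
    seen = {next(iter(vox))}
    frontier = list(seen)
    while frontier:
        cur = np.asarray(frontier.pop())
        for off in offsets:
            nxt = tuple(int(v) for v in cur + off)
            if nxt in vox and nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return len(seen) == len(vox)


# ---------------------------------------------------------------------------
# LC slab
# ---------------------------------------------------------------------------

def gen_lc_slab(shape: tuple[int, int, int],
                lc_mask: np.ndarray,
                ref_mask: np.ndarray,
                planted_cluster: Sequence[tuple[int, int, int]],
                contrast: float = 0.3,
                noise_sd: float = 0.0,
                seed: int = 0,
                baseline: float = 100.0,
                ) -> tuple[BrainVolume, BrainVolume, BrainVolume, dict]:
    """Slab with a planted bright contiguous voxel set inside the LC mask.

    All voxels start at ``baseline``; the planted voxels are raised to
    ``baseline * (1 + contrast)`` so their per-slice contrast ratio against
    the reference equals ``contrast`` exactly when ``noise_sd == 0``.
    Gaussian noise of sd ``noise_sd * baseline`` is added everywhere.
    """
    lc_mask = np.asarray(lc_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if lc_mask.shape != tuple(shape) or ref_mask.shape != tuple(shape):
        raise SimSpecError("mask shape does not match slab shape")
    cluster = [tuple(int(v) for v in p) for p in planted_cluster]
    for p in cluster:
        if not lc_mask[p]:
            raise SimSpecError(f"planted voxel {p} outside the LC mask")
    if not _is_connected(cluster):
        raise SimSpecError("planted cluster is not 26-connected")

    rng = derive_rng(seed, "lc_slab")
    data = np.full(shape, baseline, dtype=float)
    for p in cluster:
        data[p] = baseline * (1.0 + contrast)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * baseline, size=shape)
    affine = np.diag([0.4, 0.4, 3.0, 1.0])  # slab-like anisotropic voxels
    slab = BrainVolume(data, affine)
    truth = {
        "contrast": contrast, "noise_sd": noise_sd, "baseline": baseline,
        "planted_cluster": cluster, "seed": seed,
    }
    return (slab, BrainVolume(lc_mask.astype(float), affine),
            BrainVolume(ref_mask.astype(float), affine), truth)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Planted-effect cohort: LC -> follow-up tau, LC x Abeta interaction,
    and a mediated LC -> tau -> cognition path."""

    n_subjects: int = 77
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    mtl_cluster_voxels: list = field(default_factory=list)
    interaction_cluster_voxels: list | None = None
    beta_lc_tau: float = 0.5
    beta_interaction: float = 0.0
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c_prime: float = 0.1
    noise_sd_tau: float = 0.2
    noise_sd_cog: float = 0.5
    abeta_means: tuple[float, float] = (1.1, 1.6)
    abeta_sds: tuple[float, float] = (0.05, 0.10)
    abeta_weight: float = 0.8  # weight of the lower (negative) component
    age_effect: float = 0.0
    sex_effect: float = 0.0
    tau_intercept: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mtl_cluster_voxels:
            self.mtl_cluster_voxels = make_blob(
                self.grid_shape,
                tuple(s // 2 for s in self.grid_shape), radius=2)
        self.mtl_cluster_voxels = [tuple(int(v) for v in p)
                                   for p in self.mtl_cluster_voxels]
        shape = np.asarray(self.grid_shape)
        for p in self.mtl_cluster_voxels:
            if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) >= shape):
                raise SimSpecError(
                    f"cluster voxel {p} outside grid {self.grid_shape}")
        if not _is_connected(self.mtl_cluster_voxels):
            raise SimSpecError("mtl cluster is not connected")
        if self.noise_sd_tau <= 0 or self.noise_sd_cog <= 0:
            raise SimSpecError("noise sds must be > 0")
        if not 0 < self.abeta_weight < 1:
            raise SimSpecError("abeta mixture weight must be in (0, 1)")


def gen_cohort(spec: CohortSimSpec):
    """Cohort table plus per-subject baseline/follow-up tau volumes.

    Follow-up tau in the planted cluster is
    ``intercept + beta_lc_tau*LC + beta_interaction*LC*(Abeta - mean) +
    age/sex effects + noise``. The cognitive path is planted through a
    scalar MTL-tau mediator: ``mtl_tau_fu = a*LC + noise`` and
    ``pacc5_fu = b*mtl_tau_fu + c'*LC + noise``, so the planted indirect
    effect is exactly ``a*b``.

    Returns ``(cohort, baseline_vols, followup_vols, mask, truth)``.
    """
    rng = derive_rng(spec.seed, "cohort")
    n = spec.n_subjects
    shape = spec.grid_shape
    affine = np.diag([2.0, 2.0, 2.0, 1.0])

    age = rng.uniform(42.0, 90.0, size=n)
    sex = rng.binomial(1, 0.65, size=n)  # 1 = female
    educ = rng.integers(8, 21, size=n).astype(float)
    cdr = np.where(rng.random(n) < 0.95, 0.0, 0.5)
    comp = rng.random(n) < spec.abeta_weight
    abeta = np.where(
        comp,
        rng.normal(spec.abeta_means[0], spec.abeta_sds[0], size=n),
        rng.normal(spec.abeta_means[1], spec.abeta_sds[1], size=n),
    )
    lc_bl = rng.normal(0.0, 1.0, size=n)            # intensity_r scale
    lc_fu = lc_bl + rng.normal(0.03, 0.02, size=n)  # drifts worse over time

    age_c = age - age.mean()
    abeta_c = abeta - abeta.mean()

    cluster_idx = tuple(np.array(spec.mtl_cluster_voxels).T)
    inter_vox = (spec.interaction_cluster_voxels
                 if spec.interaction_cluster_voxels is not None
                 else spec.mtl_cluster_voxels)
    inter_idx = tuple(np.array([tuple(p) for p in inter_vox]).T)

    baseline_vols, followup_vols = [], []
    for i in range(n):
        base = spec.tau_intercept + rng.normal(
            0.0, spec.noise_sd_tau, size=shape)
        fu = spec.tau_intercept + rng.normal(
            0.0, spec.noise_sd_tau, size=shape)
        fu += spec.age_effect * age_c[i] + spec.sex_effect * sex[i]
        fu[cluster_idx] += spec.beta_lc_tau * lc_bl[i]
        fu[inter_idx] += spec.beta_interaction * lc_bl[i] * abeta_c[i]
        baseline_vols.append(BrainVolume(base, affine))
        followup_vols.append(BrainVolume(fu, affine))

    mtl_tau_fu = (spec.mediation_a * lc_bl
                  + rng.normal(0.0, spec.noise_sd_tau, size=n))
    pacc5_bl = rng.normal(0.0, spec.noise_sd_cog, size=n)
    pacc5_fu = (spec.mediation_b * mtl_tau_fu
                + spec.mediation_c_prime * lc_bl
                + rng.normal(0.0, spec.noise_sd_cog, size=n))

    cohort = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "age": age, "sex": sex, "educ": educ, "cdr": cdr,
        "pib_dvr": abeta,
        "intensity_r_bl": lc_bl, "intensity_r_fu": lc_fu,
        "mtl_tau_fu": mtl_tau_fu,
        "pacc5_bl": pacc5_bl, "pacc5_fu": pacc5_fu,
    })
    mask = BrainVolume(np.ones(shape), affine)
    truth = {
        "beta_lc_tau": spec.beta_lc_tau,
        "beta_interaction": spec.beta_interaction,
        "mediation_a": spec.mediation_a,
        "mediation_b": spec.mediation_b,
        "mediation_c_prime": spec.mediation_c_prime,
        "indirect": spec.mediation_a * spec.mediation_b,
        "mtl_cluster_voxels": [list(p) for p in spec.mtl_cluster_voxels],
        "abeta_means": list(spec.abeta_means),
        "abeta_sds": list(spec.abeta_sds),
        "abeta_weight": spec.abeta_weight,
        "seed": spec.seed,
    }
    return cohort, baseline_vols, followup_vols, mask, truth


# ---------------------------------------------------------------------------
# Tangles
# ---------------------------------------------------------------------------

@dataclass
class TangleSimSpec:
    """Ex vivo tangle tables with planted concordance proportions."""

    n_subjects: int = 160
    p_lc_only: float = 0.20
    p_hipp_only: float = 0.05
    p_both: float = 0.75
    lc_cutoff: float = 0.143
    region_cutoff: float = 2.757
    lc_braak0_max: float = 0.379
    density_scale_lc: float = 1.0
    density_scale_region: float = 1.0
    abeta_shift_high_braak: float = 2.0
    within_subject_rho: float = 0.6
    region_name: str = "hippocampus"
    seed: int = 0

    def __post_init__(self) -> None:
        ps = (self.p_lc_only, self.p_hipp_only, self.p_both)
        if any(p < 0 for p in ps) or sum(ps) > 1 + 1e-12:
            raise SimSpecError("class proportions must be >= 0 and sum <= 1")
        if self.density_scale_lc <= 0 or self.density_scale_region <= 0:
            raise SimSpecError("density scales must be > 0")
        if not self.lc_cutoff < self.lc_braak0_max:
            raise SimSpecError("lc_cutoff must lie below lc_braak0_max")


def gen_tangles(spec: TangleSimSpec) -> tuple[pd.DataFrame, dict]:
    """Tangle table with per-subject class drawn from the spec proportions.

    Densities are drawn below/above the planted cutoffs according to the
    class; Braak stage follows the regional density (region-high subjects
    land at stage III+), and every Braak-0 subject's LC density lies below
    the planted ``lc_braak0_max`` bound by construction.
    """
    rng = derive_rng(spec.seed, "tangles")
    n = spec.n_subjects
    p_low_low = 1.0 - (spec.p_lc_only + spec.p_hipp_only + spec.p_both)
    classes = rng.choice(
        np.array(["low_low", "lc_only", "region_only", "both"]),
        size=n,
        p=[p_low_low, spec.p_lc_only, spec.p_hipp_only, spec.p_both],
    )
    lc_high = np.isin(classes, ["lc_only", "both"])
    rg_high = np.isin(classes, ["region_only", "both"])

    s_lc = spec.density_scale_lc
    s_rg = spec.density_scale_region
    # Gaussian copula: a shared per-subject severity correlates the two
    # densities within class bands without disturbing the uniform in-band
    # marginals (so the planted class proportions stay exact)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    from scipy.stats import norm as _norm
    rho_w = spec.within_subject_rho
    u_lc = _norm.cdf(z1)
    u_rg = _norm.cdf(rho_w * z1 + np.sqrt(1 - rho_w ** 2) * z2)

    def _band(u, high, lo_hi_high, lo_hi_low):
        lo = np.where(high, lo_hi_high[0], lo_hi_low[0])
        hi = np.where(high, lo_hi_high[1], lo_hi_low[1])
        return lo + u * (hi - lo)

    lc_density = _band(
        u_lc, lc_high,
        (spec.lc_cutoff * 1.05, spec.lc_braak0_max * 3.0),
        (0.0, spec.lc_cutoff * 0.95)) * s_lc
    region_density = _band(
        u_rg, rg_high,
        (spec.region_cutoff * 1.05, spec.region_cutoff * 4.0),
        (0.0, spec.region_cutoff * 0.95)) * s_rg

    # Braak rule: high regional tangles -> stage III+; otherwise stage 0-II,
    # with stage 0 reserved for LC densities below the planted bound.
    braak = np.zeros(n, dtype=int)
    braak[rg_high] = rng.integers(3, 7, size=int(rg_high.sum()))
    low_rg = ~rg_high
    under_bound = lc_density < spec.lc_braak0_max * s_lc
    braak[low_rg & under_bound] = rng.integers(
        0, 3, size=int((low_rg & under_bound).sum()))
    braak[low_rg & ~under_bound] = rng.integers(
        1, 3, size=int((low_rg & ~under_bound).sum()))

    abeta = rng.gamma(2.0, 1.0, size=n)
    abeta[braak >= 3] += spec.abeta_shift_high_braak
    group = np.where(rng.random(n) < np.where(braak >= 3, 0.7, 0.2),
                     "impaired", "unimpaired")
    table = pd.DataFrame({
        "subject_id": [f"map-{i:03d}" for i in range(n)],
        "group": group,
        "age": rng.uniform(73.0, 101.0, size=n),
        "sex": rng.binomial(1, 0.66, size=n),
        "pmi": rng.uniform(3.0, 20.0, size=n),
        "braak": braak,
        "lc_tangle_density": lc_density,
        "lc_neuron_density": rng.uniform(10.0, 40.0, size=n),
        spec.region_name: region_density,
        "abeta_pct": abeta,
    })
    truth = {
        "p_low_low": p_low_low, "p_lc_only": spec.p_lc_only,
        "p_region_only": spec.p_hipp_only, "p_both": spec.p_both,
        "lc_cutoff": spec.lc_cutoff * s_lc,
        "region_cutoff": spec.region_cutoff * s_rg,
        "lc_braak0_max_bound": spec.lc_braak0_max * s_lc,
        "classes": classes.tolist(),
        "abeta_shift_high_braak": spec.abeta_shift_high_braak,
        "seed": spec.seed,
    }
    return table, truth


def gen_threshold_fixture(lc_max: float = 0.379,
                          lc_mean: float = 0.143,
                          region_max: float = 7.91,
                          region_mean: float = 2.757,
                          region_name: str = "hippocampus") -> pd.DataFrame:
    """Minimal tangle table whose derived cutoffs equal the given constants.

    Constructed so that: the maximum LC density at Braak 0 is exactly
    ``lc_max``; the unimpaired subjects strictly below it average exactly
    ``lc_mean``; and likewise for the region at Braak <= II. Useful as a
    deterministic end-to-end check of the two-step cutoff derivation.
    """
    if not 0 < lc_mean < lc_max:
        raise SimSpecError("need 0 < lc_mean < lc_max")
    if not 0 < region_mean < region_max:
        raise SimSpecError("need 0 < region_mean < region_max")
    d_lc = 0.5 * min(lc_mean, lc_max - lc_mean)
    d_rg = 0.5 * min(region_mean, region_max - region_mean)
    rows = [
        # Braak-0 subjects carrying the LC maximum
        {"group": "impaired", "braak": 0,
         "lc_tangle_density": lc_max, region_name: region_mean},
        {"group": "impaired", "braak": 0,
         "lc_tangle_density": 0.5 * lc_mean, region_name: 0.5 * region_mean},
        # Braak-II subject carrying the region maximum
        {"group": "impaired", "braak": 2,
         "lc_tangle_density": 2.0 * lc_max, region_name: region_max},
        # unimpaired pair symmetric about both target means
        {"group": "unimpaired", "braak": 1,
         "lc_tangle_density": lc_mean - d_lc,
         region_name: region_mean - d_rg},
        {"group": "unimpaired", "braak": 1,
         "lc_tangle_density": lc_mean + d_lc,
         region_name: region_mean + d_rg},
    ]
    table = pd.DataFrame(rows)
    table.insert(0, "subject_id", [f"fx-{i}" for i in range(len(table))])
    table["age"] = 85.0
    table["sex"] = 1
    table["pmi"] = 8.0
    table["lc_neuron_density"] = 20.0
    table["abeta_pct"] = 1.0
    return table


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Multi-donor expression data with planted LC-region correlations,
    planted top-fraction overlaps and a planted risk-gene overlap."""

    n_genes: int = 2000
    n_regions: int = 20       # including the seed LC region
    n_donors: int = 3
    samples_per_region: int = 3
    correlated_regions: list = field(default_factory=list)  # (name, r)
    planted_shared_top_genes: dict = field(default_factory=dict)
    risk_gene_list_size: int = 50
    planted_risk_overlap: int = 0
    top_fraction: float = 0.05
    probes_per_gene: int = 2
    donor_noise_sd: float = 0.02
    probe_noise_sd: float = 0.02
    sample_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.correlated_regions:
            if not -1 < r < 1:
                raise SimSpecError(f"target r for {name} outside (-1, 1)")
        top_k = int(np.floor(self.top_fraction * self.n_genes))
        for name, k in self.planted_shared_top_genes.items():
            if k > top_k:
                raise SimSpecError(
                    f"{k} planted top genes for {name} exceed the "
                    f"top-fraction set size {top_k}")
        if self.planted_risk_overlap > self.risk_gene_list_size:
            raise SimSpecError("planted risk overlap exceeds risk list size")


def _region_names(spec: ExpressionSimSpec) -> list[str]:
    names = ["LC"] + [name for name, _ in spec.correlated_regions]
    i = 1
    while len(names) < spec.n_regions:
        cand = f"region{i:02d}"
        if cand not in names:
            names.append(cand)
        i += 1
    return names[:spec.n_regions]


def gen_expression(spec: ExpressionSimSpec):
    """Probe-level multi-donor matrices plus atlas and truth record.

    Group-level region profiles are built first: each correlated region is
    ``r * LC + sqrt(1 - r^2) * noise`` so its realized Pearson correlation
    with the LC approaches the target as ``n_genes`` grows. Planted shared
    top genes are then raised above every other value in both the LC and
    the region's column; risk-list filler genes are clamped below the
    60th percentile everywhere so they can never enter a top set.

    Returns a dict with keys ``donor_probe_matrices``, ``probe_map``,
    ``donor_sample_coords``, ``donor_sample_labels``, ``atlas``,
    ``label_names``, ``risk_genes``, ``group_values``, ``truth``.
    """
    rng = derive_rng(spec.seed, "expression")
    names = _region_names(spec)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    ngenes = spec.n_genes

    lc = rng.standard_normal(ngenes)
    values = {"LC": lc}
    targets = dict(spec.correlated_regions)
    for name in names[1:]:
        if name in targets:
            r = targets[name]
            noise = rng.standard_normal(ngenes)
            values[name] = r * lc + np.sqrt(1 - r * r) * noise
        else:
            values[name] = rng.standard_normal(ngenes)
    group = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))

    # plant shared top genes: push them above everything in LC + the region
    used: set[str] = set()
    planted_sets: dict[str, list[str]] = {}
    for name, k in spec.planted_shared_top_genes.items():
        if name not in group.columns:
            raise SimSpecError(f"unknown region {name!r} for top planting")
        pool = [g for g in genes if g not in used]
        chosen = list(rng.choice(pool, size=k, replace=False))
        used.update(chosen)
        bump = max(group["LC"].max(), group[name].max()) + 1.0
        for j, g in enumerate(chosen):
            group.loc[g, "LC"] = bump + (k - j) * 0.01
            group.loc[g, name] = bump + (k - j) * 0.01
        planted_sets[name] = sorted(chosen)

    # risk gene list: planted overlap from the planted top genes (or, if
    # none were planted, from the realized top union), fillers clamped low
    union_planted = sorted(used)
    risk: list[str] = []
    if spec.planted_risk_overlap > 0:
        if len(union_planted) < spec.planted_risk_overlap:
            raise SimSpecError(
                "planted risk overlap requires at least that many planted "
                "shared top genes")
        risk = list(rng.choice(union_planted,
                               size=spec.planted_risk_overlap,
                               replace=False))
    n_fill = spec.risk_gene_list_size - len(risk)
    filler_pool = [g for g in genes if g not in used and g not in risk]
    fillers = list(rng.choice(filler_pool, size=n_fill, replace=False))
    q60 = group.quantile(0.60)
    for g in fillers:
        for col in group.columns:
            if group.loc[g, col] > q60[col]:
                group.loc[g, col] = q60[col] - rng.uniform(0.0, 0.1)
    risk = sorted(risk + fillers)

    # atlas: one 2x2x2 voxel block per region on a small grid
    n_side = int(np.ceil(len(names) ** (1 / 3)))
    grid = tuple(max(4, 2 * n_side + 2) for _ in range(3))
    atlas_data = np.zeros(grid)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    label_names = {}
    blocks = {}
    positions = list(np.ndindex(n_side, n_side, n_side))
    for lab, name in enumerate(names, start=1):
        bi, bj, bk = positions[lab - 1]
        sl = (slice(2 * bi, 2 * bi + 2), slice(2 * bj, 2 * bj + 2),
              slice(2 * bk, 2 * bk + 2))
        atlas_data[sl] = lab
        label_names[lab] = name
        blocks[name] = np.argwhere(atlas_data == lab)
    atlas = BrainVolume(atlas_data, affine)

    # donor-level probe matrices and sample coordinates
    probe_rows = []
    for g in genes:
        for p in range(spec.probes_per_gene):
            probe_rows.append((f"{g}_p{p}", g))
    probe_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene_id"])

    donor_probe_matrices = []
    donor_sample_coords = []
    donor_sample_labels = []
    for d in range(spec.n_donors):
        donor_vals = group + rng.normal(
            0.0, spec.donor_noise_sd, size=group.shape)
        cols, coords, labs = {}, [], []
        s_id = 0
        for lab, name in label_names.items():
            vox = blocks[name]
            for s in range(spec.samples_per_region):
                v = vox[s % len(vox)]
                mm = (affine @ np.append(v, 1.0))[:3]
                coords.append(mm)
                labs.append(lab)
                sample = donor_vals[name] + rng.normal(
                    0.0, spec.sample_noise_sd, size=ngenes)
                probe_vals = np.repeat(
                    sample.to_numpy()[:, None], spec.probes_per_gene, axis=1
                ) + rng.normal(0.0, spec.probe_noise_sd,
                               size=(ngenes, spec.probes_per_gene))
                cols[f"d{d}_s{s_id:04d}"] = probe_vals.ravel()
                s_id += 1
        mat = pd.DataFrame(
            cols,
            index=pd.Index([f"{g}_p{p}" for g in genes
                            for p in range(spec.probes_per_gene)],
                           name="probe_id"),
        )
        donor_probe_matrices.append(mat)
        donor_sample_coords.append(np.asarray(coords))
        donor_sample_labels.append(np.asarray(labs))

    truth = {
        "targets": {name: float(r) for name, r in spec.correlated_regions},
        "realized_r": {
            name: float(np.corrcoef(group["LC"], group[name])[0, 1])
            for name in names[1:]
        },
        "planted_shared_top_genes": planted_sets,
        "risk_genes": risk,
        "planted_risk_overlap": spec.planted_risk_overlap,
        "seed": spec.seed,
    }
    return {
        "donor_probe_matrices": donor_probe_matrices,
        "probe_map": probe_map,
        "donor_sample_coords": donor_sample_coords,
        "donor_sample_labels": donor_sample_labels,
        "atlas": atlas,
        "label_names": label_names,
        "risk_genes": risk,
        "group_values": group,
        "truth": truth,
    }
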