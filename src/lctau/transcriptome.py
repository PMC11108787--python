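"""Imaging-transcriptomics: probe aggregation, sample-to-region assignment,
median regional profiles, seed-region similarity with a permutation null,
top-fraction gene sets and risk-gene overlap probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .core_io import BrainVolume
from .exceptions import UndefinedCorrelationError

__all__ = [
    "ExpressionMatrix",
    "SimilarityProfile",
    "GeneSetIntersection",
    "aggregate_probes",
    "assign_samples",
    "regional_medians",
    "similarity_profile",
    "top_fraction_set",
    "intersect_with_seed",
    "risk_overlap_probability",
]


@dataclass
class ExpressionMatrix:
    """Group-level genes x regions matrix with provenance."""

    values: pd.DataFrame  # index = gene ids, columns = region labels
    n_donors: int = 1
    samples_per_region: dict = field(default_factory=dict)
    missing_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicated gene ids: {list(dup[:5])}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SimilarityProfile:
    seed_region: str
    r: pd.Series                  # per-region Pearson r (seed excluded)
    perm_p: pd.Series
    n_perm: int
    undefined_regions: list = field(default_factory=list)

    def top_regions(self, k: int = 5) -> list[str]:
        return list(self.r.sort_values(ascending=False).index[:k])


@dataclass
class GeneSetIntersection:
    seed_region: str
    pair_sets: dict               # region -> sorted list of genes
    union: list
    background_size: int

    @property
    def pair_sizes(self) -> dict:
        return {k: len(v) for k, v in self.pair_sets.items()}


def aggregate_probes(probe_matrix: pd.DataFrame,
                     probe_to_gene: pd.Series | dict) -> pd.DataFrame:
    """Mean-average multi-probe rows into one row per gene.

    ``probe_to_gene`` maps probe id -> gene id; probes without a mapping
    are dropped, and genes keep the order of first appearance sorted by id.
    """
    mapping = pd.Series(probe_to_gene)
    known = probe_matrix.index.intersection(mapping.index)
    sub = probe_matrix.loc[known]
    genes = mapping.loc[known]
    out = sub.groupby(genes.to_numpy()).mean()
    out.index.name = "gene_id"
    return out.sort_index()


def assign_samples(sample_coords_mm: np.ndarray, atlas: BrainVolume,
                   max_dist_mm: float = 3.0) -> np.ndarray:
    """Region label per sample (0 = unassigned).

    A sample inside a labeled voxel takes that voxel's label; otherwise it
    takes the label of the nearest labeled voxel center if strictly closer
    than ``max_dist_mm`` (ties broken by the smallest label id).
    """
    coords = np.asarray(sample_coords_mm, dtype=float)
    if coords.ndim == 1:
        coords = coords[None, :]
    labels_vol = np.rint(atlas.data).astype(int)
    inv = np.linalg.inv(atlas.affine)
    shape = np.asarray(atlas.shape)

    lab_idx = np.argwhere(labels_vol > 0)
    if lab_idx.size == 0:
        return np.zeros(len(coords), dtype=int)
    hom = np.column_stack([lab_idx, np.ones(len(lab_idx))])
    centers_mm = (atlas.affine @ hom.T).T[:, :3]
    tree = cKDTree(centers_mm)
    lab_vals = labels_vol[tuple(lab_idx.T)]

    out = np.zeros(len(coords), dtype=int)
    vox = (inv @ np.column_stack([coords, np.ones(len(coords))]).T).T[:, :3]
    ijk = np.rint(vox).astype(int)
    for s in range(len(coords)):
        inside = np.all((ijk[s] >= 0) & (ijk[s] < shape))
        if inside:
            lab = labels_vol[tuple(ijk[s])]
            if lab > 0:
                out[s] = lab
                continue
        near = tree.query_ball_point(coords[s], r=max_dist_mm)
        if not near:
            continue
        d = np.linalg.norm(centers_mm[near] - coords[s], axis=1)
        dmin = d.min()
        if dmin >= max_dist_mm:
            continue
        tied = [near[i] for i in range(len(near))
                if d[i] <= dmin + 1e-9]
        out[s] = int(min(lab_vals[t] for t in tied))
    return out


def regional_medians(donor_matrices: list[pd.DataFrame],
                     donor_labels: list[np.ndarray],
                     label_names: dict[int, str] | None = None,
                     ) -> ExpressionMatrix:
    """Median within region per donor, then median across donors.

    ``donor_matrices[d]`` is genes x samples for donor ``d`` and
    ``donor_labels[d]`` gives each sample's integer region label
    (0 = unassigned, excluded). Regions with no contributing sample in any
    donor are flagged missing rather than silently dropped from provenance.
    """
    if len(donor_matrices) != len(donor_labels):
        raise ValueError("one label vector per donor matrix required")
    all_labels = sorted({int(l) for labs in donor_labels
                         for l in np.unique(labs) if l > 0})
    per_donor: list[pd.DataFrame] = []
    samples_per_region: dict[int, int] = {}
    for mat, labs in zip(donor_matrices, donor_labels):
        labs = np.asarray(labs)
        if mat.shape[1] != labs.size:
            raise ValueError("label vector length != number of samples")
        cols = {}
        for lab in all_labels:
            sel = labs == lab
            if sel.any():
                cols[lab] = mat.iloc[:, np.flatnonzero(sel)].median(axis=1)
                samples_per_region[lab] = (samples_per_region.get(lab, 0)
                                           + int(sel.sum()))
        per_donor.append(pd.DataFrame(cols, index=mat.index))

    group_cols = {}
    for lab in all_labels:
        donor_series = [d[lab] for d in per_donor if lab in d.columns]
        group_cols[lab] = pd.concat(donor_series, axis=1).median(axis=1)
    values = pd.DataFrame(group_cols, index=donor_matrices[0].index)

    missing: list[str] = []
    if label_names is not None:
        values = values.rename(columns=label_names)
        spr = {label_names.get(k, str(k)): v
               for k, v in samples_per_region.items()}
        missing = [name for lab, name in label_names.items()
                   if lab not in all_labels]
    else:
        values.columns = [str(c) for c in values.columns]
        spr = {str(k): v for k, v in samples_per_region.items()}
    values.index.name = "gene_id"
    return ExpressionMatrix(values=values, n_donors=len(donor_matrices),
                            samples_per_region=spr, missing_regions=missing)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def similarity_profile(expr: ExpressionMatrix, seed_region: str = "LC",
                       n_perm: int = 10_000,
                       seed: int | np.random.Generator = 0,
                       ) -> SimilarityProfile:
    """Pearson similarity of the seed region's gene profile to every other.

    The permutation null shuffles the partner column's gene assignment
    ``n_perm`` times per region (the seed stays fixed) and
    ``perm_p = (1 + #{|r_null| >= |r_obs|}) / (n_perm + 1)``. Constant
    partner columns get NaN r and are flagged.
    """
    if seed_region not in expr.values.columns:
        raise KeyError(f"seed region {seed_region!r} not in matrix")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    s = expr.values[seed_region].to_numpy(dtype=float)
    sc = s - s.mean()
    s_norm = np.sqrt(sc @ sc)
    if s_norm == 0:
        raise UndefinedCorrelationError("seed region column is constant")
    n_genes = s.size
    partners = [c for c in expr.values.columns if c != seed_region]
    r_obs, perm_p, undefined = {}, {}, []
    for region in partners:
        v = expr.values[region].to_numpy(dtype=float)
        vc = v - v.mean()
        v_norm = np.sqrt(vc @ vc)
        if v_norm == 0:
            r_obs[region] = np.nan
            perm_p[region] = np.nan
            undefined.append(region)
            continue
        r = float(sc @ vc / (s_norm * v_norm))
        r_obs[region] = r
        # vectorized permutation null: r under shuffled gene assignment
        perm = rng.permuted(
            np.tile(np.arange(n_genes), (n_perm, 1)), axis=1)
        r_null = (vc[perm] @ sc) / (s_norm * v_norm)
        perm_p[region] = float(
            (1 + np.sum(np.abs(r_null) >= abs(r))) / (n_perm + 1))
    return SimilarityProfile(
        seed_region=seed_region,
        r=pd.Series(r_obs, name="r"),
        perm_p=pd.Series(perm_p, name="perm_p"),
        n_perm=n_perm,
        undefined_regions=undefined,
    )


def top_fraction_set(expr: ExpressionMatrix, region: str,
                     fraction: float = 0.05) -> list[str]:
    """The floor(fraction * n_genes) highest-expressed genes in a region.

    Boundary ties are broken deterministically by ascending gene id.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    col = expr.values[region]
    k = int(np.floor(fraction * len(col)))
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return sorted(order[:k])


def intersect_with_seed(expr: ExpressionMatrix, seed_region: str,
                        partner_regions: list[str],
                        fraction: float = 0.05) -> GeneSetIntersection:
    """Pairwise top-fraction intersections with the seed, plus their union."""
    seed_top = set(top_fraction_set(expr, seed_region, fraction))
    pair_sets = {}
    union: set[str] = set()
    for region in partner_regions:
        pair = seed_top & set(top_fraction_set(expr, region, fraction))
        pair_sets[region] = sorted(pair)
        union |= pair
    return GeneSetIntersection(
        seed_region=seed_region, pair_sets=pair_sets,
        union=sorted(union), background_size=len(expr.gene_ids),
    )


def risk_overlap_probability(union_set, risk_list, background_genes,
                             n_draws: int = 10_000,
                             seed: int | np.random.Generator = 0,
                             ) -> tuple[int, float]:
    """One-tailed Monte-Carlo probability of the observed risk-gene overlap.

    Draws ``n_draws`` gene sets of size ``|union_set|`` uniformly without
    replacement from the background and returns
    ``(observed_overlap, (1 + #{draw >= observed}) / (n_draws + 1))``.
    Risk genes outside the background are dropped with a warning.
    """
    background = list(dict.fromkeys(background_genes))
    bg_set = set(background)
    union = [g for g in dict.fromkeys(union_set)]
    if not set(union) <= bg_set:
        raise ValueError("union_set contains genes outside the background")
    risk = [g for g in dict.fromkeys(risk_list)]
    outside = [g for g in risk if g not in bg_set]
    if outside:
        warnings.warn(
            f"{len(outside)} risk gene(s) outside the background dropped"
        )
        risk = [g for g in risk if g in bg_set]
    observed = len(set(union) & set(risk))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_bg, k = len(background), len(union)
    risk_mask = np.isin(np.array(background), np.array(risk)) \
        if risk else np.zeros(n_bg, dtype=bool)
    count = 0
    for _ in range(n_draws):
        draw = rng.choice(n_bg, size=k, replace=False)
        if int(risk_mask[draw].sum()) >= observed:
            count += 1
    p = (1 + count) / (n_draws + 1)
    return observed, float(p)
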