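"""Gene-set enrichment statistics from first principles.

Cohort-level GSEA: genes are ranked by signal-to-noise between two
phenotype groups, each gene set is scored by the extremum of a weighted
Kolmogorov-Smirnov running sum, and significance comes from a phenotype
permutation null with sign-matched NES normalization and the NES-ratio
FDR. Per-sample (per-spot) scores use the ssGSEA rank-weighted running
difference.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be nonempty")
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    size: int


def group_by_median(scores) -> np.ndarray:
    """Binary labels: 1 (high) iff score strictly exceeds the median;
    ties at the median go to the low group."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValidationError("need at least 2 samples")
    return (scores > np.median(scores)).astype(int)


def signal_to_noise(matrix: np.ndarray, labels: np.ndarray,
                    sigma_floor: float = 0.2) -> np.ndarray:
    """Per-gene (mu1 - mu0) / (s1 + s0) with each class s floored at
    max(sigma_floor * |mu|, sigma_floor * eps-scale) as in classic GSEA."""
    x1 = matrix[:, labels == 1]
    x0 = matrix[:, labels == 0]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    s1, s0 = x1.std(axis=1, ddof=1), x0.std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(sigma_floor * np.abs(m1), sigma_floor))
    s0 = np.maximum(s0, np.maximum(sigma_floor * np.abs(m0), sigma_floor))
    return (m1 - m0) / (s1 + s0)


def _es_scores(metric: np.ndarray, order: np.ndarray, hits: np.ndarray,
               weight: float) -> np.ndarray:
    """Enrichment scores for all sets given one ranking.

    metric: (N,) ranking metric per gene; order: indices sorting it
    descending; hits: (S, N) boolean membership in gene order.
    """
    n = metric.size
    h = hits[:, order]
    w = np.abs(metric[order]) ** weight if weight != 0 else np.ones(n)
    numer = h * w
    denom = numer.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    p_hit = np.cumsum(numer, axis=1) / denom
    n_hit = h.sum(axis=1, keepdims=True)
    p_miss = np.cumsum(~h, axis=1) / np.maximum(n - n_hit, 1)
    d = p_hit - p_miss
    idx = np.argmax(np.abs(d), axis=1)
    return d[np.arange(d.shape[0]), idx]


def gsea(matrix: pd.DataFrame, labels, sets: list[GeneSet], n_perm: int = 1000,
         weight: float = 1.0, seed: int = 0, min_size: int = 5) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA of ``sets`` on a genes x samples matrix.

    Returns one result per retained set (overlap with the universe >=
    ``min_size``), with permutation p, sign-matched NES and NES-ratio FDR.
    """
    if n_perm <= 0:
        raise ValidationError("n_perm must be positive")
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValidationError("both classes must be present")
    if matrix.index.has_duplicates:
        raise ValidationError("duplicate gene identifiers")
    genes = matrix.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    kept: list[GeneSet] = []
    hit_rows = []
    for s in sets:
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        if len(idx) < min_size:
            continue
        row = np.zeros(len(genes), dtype=bool)
        row[idx] = True
        kept.append(s)
        hit_rows.append(row)
    if not kept:
        raise ValidationError("no gene set overlaps the universe at min_size")
    hits = np.vstack(hit_rows)
    values = matrix.to_numpy(dtype=float)

    metric = signal_to_noise(values, labels)
    order = np.argsort(-metric, kind="stable")
    es = _es_scores(metric, order, hits, weight)

    rng = np.random.default_rng(seed)
    null_es = np.empty((n_perm, len(kept)))
    for b in range(n_perm):
        perm = rng.permutation(labels)
        m = signal_to_noise(values, perm)
        null_es[b] = _es_scores(m, np.argsort(-m, kind="stable"), hits, weight)

    results = []
    nes_obs = np.empty(len(kept))
    nes_null = np.full((n_perm, len(kept)), np.nan)
    p_vals = np.empty(len(kept))
    for j in range(len(kept)):
        same = null_es[:, j][np.sign(null_es[:, j]) == np.sign(es[j])]
        if same.size == 0 or es[j] == 0:
            p_vals[j] = 1.0
            nes_obs[j] = 0.0
            continue
        p_vals[j] = (np.sum(np.abs(same) >= abs(es[j])) + 1) / (same.size + 1)
        mean_same = np.abs(same).mean()
        nes_obs[j] = es[j] / mean_same
        pos_mean = np.abs(null_es[null_es[:, j] >= 0, j]).mean() if (null_es[:, j] >= 0).any() else np.nan
        neg_mean = np.abs(null_es[null_es[:, j] < 0, j]).mean() if (null_es[:, j] < 0).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[:, j] = np.where(null_es[:, j] >= 0,
                                      null_es[:, j] / pos_mean,
                                      -np.abs(null_es[:, j]) / neg_mean)

    flat_null = nes_null[np.isfinite(nes_null)]
    for j in range(len(kept)):
        nes = nes_obs[j]
        if nes == 0:
            fdr = 1.0
        elif nes > 0:
            num_pool = flat_null[flat_null >= 0]
            obs_pool = nes_obs[nes_obs >= 0]
            num = np.mean(num_pool >= nes) if num_pool.size else 1.0
            den = np.mean(obs_pool >= nes) if obs_pool.size else 1.0
            fdr = min(1.0, num / max(den, 1e-12))
        else:
            num_pool = flat_null[flat_null < 0]
            obs_pool = nes_obs[nes_obs < 0]
            num = np.mean(num_pool <= nes) if num_pool.size else 1.0
            den = np.mean(obs_pool <= nes) if obs_pool.size else 1.0
            fdr = min(1.0, num / max(den, 1e-12))
        results.append(EnrichmentResult(kept[j].name, float(es[j]), float(nes_obs[j]),
                                        float(p_vals[j]), float(fdr),
                                        int(hits[j].sum())))
    return results


def ssgsea(expression, genes, gene_set: GeneSet, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of one gene set.

    Genes are ranked by expression descending (rank values N..1); the
    score is the sum over ranks of the difference between the normalized
    rank^alpha-weighted in-set cumulative fraction and the uniform
    out-of-set cumulative fraction. Invariant under strictly increasing
    transforms of the expression vector.
    """
    expr = np.asarray(expression, dtype=float)
    genes = list(genes)
    if expr.size != len(genes):
        raise ValidationError("expression and gene list length mismatch")
    members = set(gene_set.genes)
    in_set = np.array([g in members for g in genes])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValidationError("gene set does not overlap the expressed genes")
    if n_hit == expr.size:
        raise ValidationError("gene set equals the whole universe")
    order = np.argsort(-expr, kind="stable")
    hit = in_set[order]
    n = expr.size
    rank_values = np.arange(n, 0, -1, dtype=float)  # N for the top gene
    w = rank_values ** alpha
    numer = np.where(hit, w, 0.0)
    p_in = np.cumsum(numer) / numer.sum()
    p_out = np.cumsum(~hit) / (n - n_hit)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(matrix: pd.DataFrame, gene_set: GeneSet,
                  alpha: float = 0.25, log_normalize: bool = True) -> pd.Series:
    """ssGSEA score per column (sample/spot) of a genes x samples matrix.

    With ``log_normalize`` the columns are library-size normalized and
    log1p-transformed first (a monotone map per sample, so it only matters
    through tie structure)."""
    values = matrix.to_numpy(dtype=float)
    if log_normalize:
        libs = values.sum(axis=0)
        libs[libs == 0] = 1.0
        values = np.log1p(values / libs * 1e4)
    genes = list(matrix.index)
    return pd.Series(
        [ssgsea(values[:, j], genes, gene_set, alpha=alpha)
         for j in range(values.shape[1])],
        index=matrix.columns, name=gene_set.name)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must be in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
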