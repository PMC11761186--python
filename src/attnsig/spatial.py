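"""Spatial-transcriptome integration of the attention signal.

Reads a Visium-style bundle, registers an attention heatmap onto spots
(mean value in the spot disc), clusters spots (library-size normalize ->
log1p -> top variable genes -> PCA -> k-means), selects the tumor cluster
by marker expression, and correlates ln(attention) with per-spot ssGSEA
enrichment via Spearman rank correlation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse, stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .enrichment import GeneSet, ValidationError, ssgsea_matrix
from .io import SpotTable


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int


def read_spatial(mtx_path, features_path, barcodes_path, positions_path,
                 scale_path) -> SpotTable:
    """Assemble a :class:`SpotTable` from a MatrixMarket triplet plus
    positions CSV and scale-factor sidecar; every count barcode must have
    a position row."""
    counts = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = Path(features_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    if counts.shape != (len(genes), len(barcodes)):
        raise ValidationError("counts shape does not match features/barcodes")
    positions = pd.read_csv(positions_path)
    pos_bc = set(positions["barcode"])
    missing = [b for b in barcodes if b not in pos_bc]
    if missing:
        raise ValidationError(f"positions missing barcodes: {missing[:3]}...")
    positions = positions.set_index("barcode").loc[barcodes].reset_index()
    scale = json.loads(Path(scale_path).read_text())
    return SpotTable(genes=genes, barcodes=barcodes, counts=counts,
                     positions=positions,
                     spot_radius_px=float(scale["spot_radius_px"]),
                     scale_factor=float(scale.get("scale_factor", 1.0)))


def register_attention_to_spots(heatmap: np.ndarray, spots: SpotTable) -> np.ndarray:
    """Per-spot attention: mean heatmap value over pixels within the spot
    radius of the scaled center; sub-pixel radii fall back to the nearest
    pixel."""
    hm = np.asarray(heatmap, dtype=float)
    h, w = hm.shape
    sf = spots.scale_factor
    cx = spots.positions["x_pixel"].to_numpy(dtype=float) * sf
    cy = spots.positions["y_pixel"].to_numpy(dtype=float) * sf
    radius = spots.spot_radius_px * sf
    if (cx < 0).any() or (cx > w - 1).any() or (cy < 0).any() or (cy > h - 1).any():
        raise ValidationError("spot center outside the heatmap")
    values = np.empty(len(cx))
    if radius < 1.0:
        iy = np.clip(np.round(cy).astype(int), 0, h - 1)
        ix = np.clip(np.round(cx).astype(int), 0, w - 1)
        return hm[iy, ix]
    m = int(np.ceil(radius))
    gy, gx = np.mgrid[-m:m + 1, -m:m + 1]
    for i, (x, y) in enumerate(zip(cx, cy)):
        yy = np.clip(np.round(y).astype(int) + gy, 0, h - 1)
        xx = np.clip(np.round(x).astype(int) + gx, 0, w - 1)
        disc = (gy ** 2 + gx ** 2) <= radius ** 2
        values[i] = hm[yy[disc], xx[disc]].mean()
    return values


def _normalized_log(spots: SpotTable) -> np.ndarray:
    """Library-size normalized log1p expression, genes x spots dense."""
    x = np.asarray(spots.counts.todense(), dtype=float)
    libs = x.sum(axis=0)
    libs[libs == 0] = 1.0
    return np.log1p(x / libs * 1e4)


def cluster_spots(spots: SpotTable, n_clusters: int, seed: int = 0,
                  n_top_genes: int = 200, n_components: int = 20) -> np.ndarray:
    """Bespoke expression clustering: normalize -> log1p -> top variable
    genes -> PCA -> seeded k-means. Deterministic per seed."""
    if n_clusters < 1:
        raise ValidationError("n_clusters must be >= 1")
    if n_clusters > spots.n_spots:
        raise ValidationError("n_clusters exceeds the number of spots")
    if n_clusters == 1:
        return np.zeros(spots.n_spots, dtype=int)
    logx = _normalized_log(spots)
    var = logx.var(axis=1)
    top = np.argsort(-var)[:min(n_top_genes, logx.shape[0])]
    feats = logx[top].T
    n_comp = min(n_components, feats.shape[1], feats.shape[0] - 1)
    if n_comp >= 2:
        feats = PCA(n_components=n_comp, random_state=seed).fit_transform(feats)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return km.fit_predict(feats)


def select_tumor_cluster(labels: np.ndarray, spots: SpotTable,
                         marker_genes: GeneSet) -> int:
    """Cluster with the highest mean normalized marker expression; ties
    resolve to the larger cluster."""
    idx = [i for i, g in enumerate(spots.genes) if g in set(marker_genes.genes)]
    if not idx:
        raise ValidationError("no marker gene found in the universe")
    logx = _normalized_log(spots)
    marker = logx[idx]
    if marker.max() == 0:
        raise ValidationError("marker genes are expressed nowhere")
    labels = np.asarray(labels)
    best_cluster, best_key = None, None
    for c in np.unique(labels):
        members = labels == c
        key = (marker[:, members].mean(), int(members.sum()))
        if best_key is None or key > best_key:
            best_key, best_cluster = key, int(c)
    return best_cluster


def spearman(x, y) -> CorrelationResult:
    """Tie-corrected Spearman rho (Pearson on mid-ranks) with a
    t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance in an input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return CorrelationResult(rho, float(min(p, 1.0)), n)


def annotate_spots(spots: SpotTable, heatmap: np.ndarray, signature: GeneSet,
                   marker_genes: GeneSet, n_clusters: int = 4,
                   seed: int = 0, alpha: float = 0.25) -> pd.DataFrame:
    """Full per-spot annotation: cluster label, tumor flag, registered
    attention and ssGSEA enrichment of the signature."""
    labels = cluster_spots(spots, n_clusters, seed=seed)
    tumor = select_tumor_cluster(labels, spots, marker_genes)
    attention = register_attention_to_spots(heatmap, spots)
    enrich = ssgsea_matrix(spots.to_frame(), signature, alpha=alpha)
    return pd.DataFrame({
        "spot_id": spots.barcodes,
        "cluster": labels,
        "is_tumor": labels == tumor,
        "attention": attention,
        "enrichment": enrich.to_numpy(),
    })


def correlate_attention_signature(annotations: pd.DataFrame,
                                  tumor_only: bool = True,
                                  epsilon: float = 1e-6) -> CorrelationResult:
    """Spearman correlation of ln(attention + epsilon) with the per-spot
    enrichment score, optionally restricted to the tumor cluster."""
    df = annotations
    if tumor_only:
        df = df[df["is_tumor"]]
    if len(df) < 3:
        raise ValidationError("need >= 3 eligible spots")
    return spearman(np.log(df["attention"].to_numpy(dtype=float) + epsilon),
                    df["enrichment"].to_numpy(dtype=float))
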