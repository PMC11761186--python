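"""Synthetic cohorts, tissue images, expression and spatial samples.

The generators plant the statistical structure the downstream analysis
assumes, so the whole pipeline can be exercised and calibrated without
any real slides or sequencing data:

* histology tiles: a pink stromal background with purple elliptical
  "tumor nests" and immune infiltrate rendered as spatial clusters of
  small dark blobs whose area fraction approximates a target density d;
* survival: exponential hazards h0 * exp(-beta * d), so denser infiltrate
  means longer survival; independent uniform truncation models censoring;
* expression: negative-binomial counts whose signature-gene means scale
  with infiltrate (per patient, or per spot for Visium-style samples).

Defaults are calibrated so the marginal median overall survival is about
35 months, matching the cohort the analysis is modeled on.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse

from .enrichment import GeneSet
from .io import SpotTable, ValidationError


class ParameterError(ValueError):
    pass


#: Baseline hazard (1/months): chosen so that with beta=2 and the default
#: uniform infiltrate distribution the marginal median OS is ~35 months.
DEFAULT_H0 = math.log(2.0) * math.e / 35.0


@dataclass
class CohortParams:
    """Distributional settings for :func:`generate_cohort`.

    ``d_alpha``/``d_beta`` parameterize the Beta distribution of the
    infiltrate density d; ``beta`` is the log-hazard effect of d (positive
    beta lowers the hazard, i.e. lengthens survival); ``censor_rate`` is
    the probability a record is censored (event flag 0, time uniformly
    shortened).
    """

    d_alpha: float = 1.0
    d_beta: float = 1.0
    h0: float = DEFAULT_H0
    beta: float = 2.0
    censor_rate: float = 0.2
    two_image_prob: float = 0.5
    nonsquare_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.d_alpha <= 0 or self.d_beta <= 0:
            raise ParameterError("Beta distribution parameters must be positive")
        if self.h0 <= 0:
            raise ParameterError("baseline hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must be in [0, 1)")


@dataclass
class Cohort:
    """A generated cohort: clinical table, per-patient ground truth and
    rendered images with their infiltrate masks."""

    clinical: pd.DataFrame
    truth: pd.DataFrame
    images: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    image_index: pd.DataFrame


STAGES = np.array(["III", "IV", "II", None], dtype=object)
STAGE_P = [0.72, 0.18, 0.05, 0.05]
RESIDUAL = np.array(["no_macroscopic", "1-10mm", "11-20mm", ">20mm"], dtype=object)
RESIDUAL_P = [0.25, 0.50, 0.10, 0.15]


def render_tissue_image(width: int, height: int, infiltrate_density: float,
                        seed: int = 0, return_tumor_mask: bool = False):
    """Render a synthetic H&E-like tile with planted immune infiltrate.

    Returns (image uint8 (H, W, 3), infiltrate mask bool (H, W)) and, when
    requested, the tumor-nest mask too. The infiltrate mask's area
    fraction approximates ``infiltrate_density``. Deterministic per seed.
    """
    if width < 32 or height < 32:
        raise ParameterError("width and height must be >= 32")
    if not 0.0 <= infiltrate_density <= 1.0:
        raise ParameterError("infiltrate density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = int(height), int(width)

    base = np.array([236.0, 205.0, 218.0])  # eosin pink
    img = np.broadcast_to(base, (h, w, 3)).copy()
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=max(2, min(h, w) / 24))
    texture = texture / (np.abs(texture).max() + 1e-9)
    img += texture[:, :, None] * np.array([8.0, 14.0, 8.0])

    yy, xx = np.mgrid[0:h, 0:w]
    tumor_mask = np.zeros((h, w), dtype=bool)
    nest_color = np.array([188.0, 142.0, 196.0])  # hematoxylin-tinted nests
    for _ in range(int(rng.integers(2, 5))):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(0.12, 0.30) * h
        rx = rng.uniform(0.12, 0.30) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        nest = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
        tumor_mask |= nest
        img[nest] = 0.45 * img[nest] + 0.55 * nest_color

    mask = np.zeros((h, w), dtype=bool)
    target = infiltrate_density * h * w
    if target > 0:
        scale = max(1.0, min(h, w) / 64.0)
        blob_color = np.array([70.0, 52.0, 118.0])  # dense basophilic blobs
        area = 0
        guard = 0
        while area < target and guard < 200000:
            ccy, ccx = rng.uniform(0, h), rng.uniform(0, w)
            for _ in range(int(rng.poisson(12)) + 1):
                guard += 1
                by = ccy + rng.normal(0, 0.07 * h)
                bx = ccx + rng.normal(0, 0.07 * w)
                r = rng.uniform(1.2, 2.6) * scale
                y0, y1 = int(max(0, by - r - 1)), int(min(h, by + r + 2))
                x0, x1 = int(max(0, bx - r - 1)), int(min(w, bx + r + 2))
                if y0 >= y1 or x0 >= x1:
                    continue
                sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
                disc = (sub_y - by) ** 2 + (sub_x - bx) ** 2 <= r * r
                new = disc & ~mask[y0:y1, x0:x1]
                area += int(new.sum())
                mask[y0:y1, x0:x1] |= disc
                region = img[y0:y1, x0:x1]
                region[disc] = 0.15 * region[disc] + 0.85 * blob_color
                if area >= target:
                    break

    img = np.clip(img + rng.normal(0, 2.0, (h, w, 3)), 0, 255).astype(np.uint8)
    if return_tumor_mask:
        return img, mask, tumor_mask
    return img, mask


def generate_cohort(n_patients: int, image_size: int = 64,
                    params: CohortParams | None = None, seed: int = 0,
                    render_images: bool = True) -> Cohort:
    """Generate a cohort of patients with planted infiltrate densities,
    exponential survival times and rendered histology images.

    Per patient: d ~ Beta(d_alpha, d_beta); OS ~ Exponential with rate
    h0 * exp(-beta * d); with probability censor_rate the record is
    censored (event 0, time uniformly shortened). One or two images are
    rendered per patient, rectangular with probability nonsquare_prob.
    """
    if n_patients < 0:
        raise ParameterError("n_patients must be >= 0")
    if n_patients and image_size < 32:
        raise ParameterError("image_size must be >= 32")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)

    cols_clin = ["patient_id", "os_months", "os_event", "pfs_months", "pfs_event",
                 "age", "stage", "residual_disease"]
    if n_patients == 0:
        empty_idx = pd.DataFrame(columns=["image_id", "patient_id"])
        return Cohort(pd.DataFrame(columns=cols_clin),
                      pd.DataFrame(columns=["patient_id", "infiltrate_density"]),
                      {}, {}, empty_idx)

    d = rng.beta(params.d_alpha, params.d_beta, n_patients)
    rate = params.h0 * np.exp(-params.beta * d)
    os_raw = rng.exponential(1.0 / rate)
    censored = rng.random(n_patients) < params.censor_rate
    os_months = np.where(censored, os_raw * rng.uniform(0, 1, n_patients), os_raw)
    pfs_months = os_months * rng.uniform(0.25, 0.75, n_patients)
    age = np.clip(np.round(rng.normal(60, 10, n_patients)), 30, 90).astype(int)
    stage = rng.choice(STAGES, size=n_patients, p=STAGE_P)
    residual = rng.choice(RESIDUAL, size=n_patients, p=RESIDUAL_P)

    pids = [f"P{i:04d}" for i in range(n_patients)]
    clinical = pd.DataFrame({
        "patient_id": pids,
        "os_months": os_months,
        "os_event": (~censored).astype(int),
        "pfs_months": pfs_months,
        "pfs_event": (~censored).astype(int),
        "age": age,
        "stage": stage,
        "residual_disease": residual,
    })
    truth = pd.DataFrame({
        "patient_id": pids,
        "infiltrate_density": d,
        "h0": params.h0,
        "beta": params.beta,
        "censor_rate": params.censor_rate,
    })

    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    rows = []
    for i, pid in enumerate(pids):
        n_img = 1 + int(rng.random() < params.two_image_prob)
        for j in range(n_img):
            nonsquare = rng.random() < params.nonsquare_prob
            wpx = 2 * image_size if nonsquare else image_size
            img_seed = int(rng.integers(0, 2 ** 31 - 1))
            image_id = f"{pid}_img{j}"
            if render_images:
                img, mask = render_tissue_image(wpx, image_size, float(d[i]),
                                                seed=img_seed)
                images[image_id] = img
                masks[image_id] = mask
            rows.append({"image_id": image_id, "patient_id": pid})
    return Cohort(clinical, truth, images, masks, pd.DataFrame(rows))


def default_gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def default_signature(n_genes: int, size: int = 40,
                      name: str = "SYN_IMMUNE_INFILTRATE_UP") -> GeneSet:
    """A synthetic immune signature: a contiguous block of the universe."""
    genes = default_gene_universe(n_genes)
    start = n_genes // 4
    return GeneSet(name, tuple(genes[start:start + size]),
                   description="synthetic infiltrate-coupled signature")


def default_tumor_markers(n_genes: int, size: int = 20) -> GeneSet:
    genes = default_gene_universe(n_genes)
    return GeneSet("SYN_TUMOR_MARKERS", tuple(genes[:size]),
                   description="synthetic tumor-nest markers")


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with var = m + dispersion * m^2."""
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


def generate_spatial_sample(image: np.ndarray, mask: np.ndarray,
                            n_genes: int, signature: GeneSet,
                            fold_change: float = 2.0, seed: int = 0,
                            tumor_mask: np.ndarray | None = None,
                            marker_genes: GeneSet | None = None,
                            marker_fold: float = 4.0,
                            pitch_px: int | None = None,
                            radius_px: float | None = None,
                            dispersion: float = 0.5,
                            libsize_sigma: float = 0.2,
                            base_mean: float = 2.0) -> SpotTable:
    """Lay a square spot lattice over ``image`` and draw counts whose
    signature-gene means scale with the infiltrate fraction inside each
    spot: mean_g *= 1 + (fold_change - 1) * f_s.

    ``tumor_mask`` (from :func:`render_tissue_image`) marks tumor nests;
    spots overlapping a nest get elevated marker-gene expression and are
    flagged in the truth table.
    """
    if fold_change <= 0:
        raise ParameterError("fold change must be > 0")
    genes = default_gene_universe(n_genes)
    universe = set(genes)
    for gs in filter(None, [signature, marker_genes]):
        missing = set(gs.genes) - universe
        if missing:
            raise ValidationError(
                f"gene set {gs.name!r} has genes outside the universe: "
                f"{sorted(missing)[:3]}...")
    h, w = mask.shape
    pitch = int(pitch_px) if pitch_px else max(8, min(h, w) // 12)
    radius = float(radius_px) if radius_px else 0.35 * pitch
    margin = int(np.ceil(radius)) + 1
    ys = np.arange(margin, h - margin, pitch)
    xs = np.arange(margin, w - margin, pitch)
    if ys.size == 0 or xs.size == 0:
        raise ValidationError("spot grid does not fit inside the image")

    rng = np.random.default_rng(seed)
    rows = []
    f_s, t_s = [], []
    gy, gx = np.mgrid[-margin:margin + 1, -margin:margin + 1]
    disc = (gy ** 2 + gx ** 2) <= radius ** 2
    for r_i, y in enumerate(ys):
        for c_i, x in enumerate(xs):
            barcode = f"SPOT-{r_i:03d}-{c_i:03d}"
            patch = mask[y - margin:y + margin + 1, x - margin:x + margin + 1]
            f = float(patch[disc].mean())
            if tumor_mask is not None:
                tpatch = tumor_mask[y - margin:y + margin + 1, x - margin:x + margin + 1]
                t = float(tpatch[disc].mean())
            else:
                t = 0.0
            rows.append({"barcode": barcode, "in_tissue": 1, "array_row": r_i,
                         "array_col": c_i, "x_pixel": int(x), "y_pixel": int(y)})
            f_s.append(f)
            t_s.append(t)
    positions = pd.DataFrame(rows)
    f_s = np.array(f_s)
    t_s = np.array(t_s)
    n_spots = len(positions)

    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    lib = rng.lognormal(mean=0.0, sigma=libsize_sigma, size=n_spots)
    mean = base[:, None] * lib[None, :]
    sig_idx = [genes.index(g) for g in signature.genes]
    mean[sig_idx] *= 1.0 + (fold_change - 1.0) * f_s[None, :]
    is_tumor = t_s > 0.5  # majority of the capture disc inside a nest
    if marker_genes is not None:
        mk_idx = [genes.index(g) for g in marker_genes.genes]
        mean[mk_idx] *= 1.0 + (marker_fold - 1.0) * is_tumor[None, :]
    counts = sparse.csr_matrix(_nb_counts(mean, dispersion, rng))

    truth = pd.DataFrame({
        "barcode": positions["barcode"],
        "spot_infiltrate": f_s,
        "tumor_frac": t_s,
        "is_tumor": is_tumor,
        "signature_fold_change": fold_change,
    })
    return SpotTable(genes=genes, barcodes=list(positions["barcode"]),
                     counts=counts, positions=positions,
                     spot_radius_px=radius, scale_factor=1.0, truth=truth)


def generate_cohort_expression(truth: pd.DataFrame, n_genes: int,
                               signature: GeneSet, fold_change: float = 2.0,
                               seed: int = 0, dispersion: float = 0.5,
                               libsize_sigma: float = 0.2,
                               base_mean: float = 5.0) -> pd.DataFrame:
    """Per-patient bulk expression (genes x patients) whose signature-gene
    means scale with each patient's infiltrate density."""
    if fold_change <= 0:
        raise ParameterError("fold change must be > 0")
    genes = default_gene_universe(n_genes)
    universe = set(genes)
    if set(signature.genes) - universe:
        raise ValidationError("signature has genes outside the universe")
    rng = np.random.default_rng(seed)
    d = truth["infiltrate_density"].to_numpy(dtype=float)
    n = d.size
    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    lib = rng.lognormal(mean=0.0, sigma=libsize_sigma, size=n)
    mean = base[:, None] * lib[None, :]
    sig_idx = [genes.index(g) for g in signature.genes]
    mean[sig_idx] *= 1.0 + (fold_change - 1.0) * d[None, :]
    counts = _nb_counts(mean, dispersion, rng)
    return pd.DataFrame(counts, index=genes, columns=list(truth["patient_id"]))


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write images (PNG), clinical.csv, truth.csv and image_index.csv."""
    from pathlib import Path

    from .io import write_image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for image_id, img in cohort.images.items():
        write_image(img, out / "images" / f"{image_id}.png")
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    cohort.image_index.to_csv(out / "image_index.csv", index=False)
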