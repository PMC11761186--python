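"""Readers and writers for the standard on-disk formats.

GMT gene-set files, the Visium-style spatial bundle (MatrixMarket counts +
features/barcodes TSV + positions CSV + scale-factor JSON), clinical CSV
tables and PNG images.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import io as spio
from scipy import sparse

from .enrichment import GeneSet, ValidationError

CLINICAL_COLUMNS = ["patient_id", "os_months", "os_event", "pfs_months",
                    "pfs_event", "age", "stage", "residual_disease"]

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                    "x_pixel", "y_pixel"]


@dataclass
class SpotTable:
    """A spatial sample: sparse counts joined to spot positions.

    ``counts`` is genes x spots; ``positions`` has one row per spot in
    barcode order with columns barcode, in_tissue, array_row, array_col,
    x_pixel, y_pixel (full-resolution pixels). ``scale_factor`` maps
    full-resolution positions onto the working image/heatmap.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sparse.csr_matrix
    positions: pd.DataFrame
    spot_radius_px: float
    scale_factor: float = 1.0
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError("counts shape does not match genes x barcodes")
        if list(self.positions["barcode"]) != list(self.barcodes):
            raise ValidationError("positions barcodes do not match count barcodes")
        if (self.counts.data < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x spots DataFrame (small samples only)."""
        return pd.DataFrame(self.counts.toarray(), index=self.genes,
                            columns=self.barcodes)


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    """Write gene sets in GMT: name <tab> description <tab> genes..."""
    names = [s.name for s in gene_sets]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate gene set names")
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(parts[0], tuple(parts[2:]), description=parts[1]))
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate gene set names in GMT")
    return sets


def write_spatial_sample(table: SpotTable, out_dir) -> Path:
    """Write the Visium-style bundle: matrix.mtx, features.tsv,
    barcodes.tsv, positions.csv and scalefactors.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(table.counts))
    (out / "features.tsv").write_text("\n".join(table.genes) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(table.barcodes) + "\n")
    table.positions.to_csv(out / "positions.csv", index=False)
    (out / "scalefactors.json").write_text(json.dumps({
        "spot_radius_px": table.spot_radius_px,
        "scale_factor": table.scale_factor,
    }))
    if table.truth is not None:
        table.truth.to_csv(out / "truth.csv", index=False)
    return out


def write_image(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def read_clinical(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("patient_id", "os_months", "os_event") if c not in df.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    return df
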