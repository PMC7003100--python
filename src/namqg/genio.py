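"""Genotype/map/phenotype I/O, marker QC and naive imputation.

Genotypes are biallelic dosage codes ``{0, 1, 2}`` counting the reference
("counted") allele, with ``-1`` for missing calls.  In NAM panels the
counted allele is, by convention, the allele carried by the alternate
founder parent of each family, so that downstream allele-substitution
effects have a stable sign anchored on the common parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

MISSING = -1


class PanelValidationError(ValueError):
    """Raised when genotype/map/family inputs are inconsistent."""


@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome and position.

    Positions may be given in centimorgans (``cm``), base pairs (``bp``)
    or both; within each chromosome they must be nondecreasing.
    """

    table: pd.DataFrame  # columns: marker, chrom, and cm and/or bp

    def __post_init__(self) -> None:
        cols = set(self.table.columns)
        if "marker" not in cols or "chrom" not in cols:
            raise PanelValidationError("map needs 'marker' and 'chrom' columns")
        if not ({"cm", "bp"} & cols):
            raise PanelValidationError("map needs a 'cm' or 'bp' position column")
        for pos_col in ("cm", "bp"):
            if pos_col not in cols:
                continue
            pos = self.table[pos_col].to_numpy(float)
            if np.any(pos < 0):
                raise PanelValidationError(f"negative {pos_col} positions in map")
            for _, grp in self.table.groupby("chrom", sort=False):
                p = grp[pos_col].to_numpy(float)
                if np.any(np.diff(p) < 0):
                    raise PanelValidationError(
                        f"map not sorted: {pos_col} decreases within a chromosome"
                    )

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(float)

    @property
    def marker(self) -> np.ndarray:
        return self.table["marker"].to_numpy(str)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MarkerPanel:
    """Genotype matrix with map and family labels.

    ``genotypes`` is an ``n x m`` int8 array of dosage codes; rows are
    individuals, columns markers.  ``family`` assigns each individual to a
    biparental family (checks and founders may carry reserved labels).
    """

    genotypes: np.ndarray
    marker_ids: np.ndarray
    map: GeneticMap
    individual_ids: np.ndarray
    family: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.family = np.asarray(self.family)
        n, m = self.genotypes.shape
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise PanelValidationError("genotype codes must be in {0,1,2} or missing")
        if len(self.marker_ids) != m:
            raise PanelValidationError(
                f"{len(self.marker_ids)} marker ids for {m} genotype columns"
            )
        if len(self.individual_ids) != n or len(self.family) != n:
            raise PanelValidationError("individual ids/family length mismatch")
        uniq, counts = np.unique(self.marker_ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise PanelValidationError(f"duplicated marker id: {dup}")
        if len(self.map) != m:
            raise PanelValidationError(
                f"map has {len(self.map)} rows for {m} markers"
            )
        if not np.array_equal(self.map.marker.astype(str), self.marker_ids.astype(str)):
            raise PanelValidationError("map marker order differs from panel columns")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, ignoring missing calls."""
        g = self.genotypes
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, g, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return p

    def subset_markers(self, keep: np.ndarray) -> "MarkerPanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MarkerPanel(
            genotypes=self.genotypes[:, idx],
            marker_ids=self.marker_ids[idx],
            map=GeneticMap(self.map.table.iloc[idx].reset_index(drop=True)),
            individual_ids=self.individual_ids,
            family=self.family,
        )

    def subset_individuals(self, keep: np.ndarray) -> "MarkerPanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return MarkerPanel(
            genotypes=self.genotypes[idx],
            marker_ids=self.marker_ids,
            map=self.map,
            individual_ids=self.individual_ids[idx],
            family=self.family[idx],
        )

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids.astype(str) == str(marker_id))
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(hits[0])


class QCResult(NamedTuple):
    panel: MarkerPanel
    n_removed: int
    n_retained: int
    n_imputed: int


def write_panel(panel: MarkerPanel, out_dir: str | Path, prefix: str = "panel") -> dict:
    """Write genotypes, map and family labels as plain-text tables.

    Genotypes go to ``<prefix>_geno.tsv`` (rows = individuals, first column
    ``id``, remaining columns named by marker id), the map to
    ``<prefix>_map.tsv`` and family labels to ``<prefix>_fam.tsv``.
    Missing calls are written as ``NA``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "geno": out_dir / f"{prefix}_geno.tsv",
        "map": out_dir / f"{prefix}_map.tsv",
        "fam": out_dir / f"{prefix}_fam.tsv",
    }
    geno = pd.DataFrame(
        panel.genotypes, columns=panel.marker_ids.astype(str)
    ).astype(object)
    geno = geno.mask(geno == MISSING, "NA")
    geno.insert(0, "id", panel.individual_ids.astype(str))
    geno.to_csv(paths["geno"], sep="\t", index=False)
    panel.map.table.to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame({"id": panel.individual_ids.astype(str), "family": panel.family}).to_csv(
        paths["fam"], sep="\t", index=False
    )
    return paths


def read_panel(geno_path: str | Path, map_path: str | Path, fam_path: str | Path) -> MarkerPanel:
    """Read and validate a genotype panel from the tab-separated dialect."""
    for p in (geno_path, map_path, fam_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    geno = pd.read_csv(geno_path, sep="\t", dtype={"id": str})
    map_tbl = pd.read_csv(map_path, sep="\t")
    fam = pd.read_csv(fam_path, sep="\t", dtype={"id": str})
    marker_ids = np.asarray(geno.columns[1:], dtype=object)
    g = geno.iloc[:, 1:].replace("NA", MISSING).to_numpy()
    g = np.where(pd.isna(g), MISSING, g).astype(np.int8)
    ids = geno["id"].to_numpy(object)
    fam_map = dict(zip(fam["id"].astype(str), fam["family"]))
    try:
        family = np.asarray([fam_map[str(i)] for i in ids])
    except KeyError as e:
        raise PanelValidationError(f"individual {e} missing from family file") from e
    return MarkerPanel(
        genotypes=g,
        marker_ids=marker_ids,
        map=GeneticMap(map_tbl),
        individual_ids=ids,
        family=family,
    )


def read_vcf(vcf_path: str | Path, fam_path: str | Path | None = None) -> MarkerPanel:
    """Read a minimal (GT-only) VCF into dosage codes.

    ``0/0`` maps to 0, ``0/1`` to 1, ``1/1`` to 2 and ``./.`` to missing.
    The counted allele is the VCF ALT allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    ids = np.asarray(vcf.samples, dtype=object)
    rows, markers, chroms, pos = [], [], [], []
    for var in vcf:
        code = np.asarray(var.gt_types, dtype=np.int8)
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        mapped = np.select(
            [code == 0, code == 1, code == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        rows.append(mapped)
        markers.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
    g = np.column_stack(rows) if rows else np.empty((len(ids), 0), dtype=np.int8)
    map_tbl = pd.DataFrame({"marker": markers, "chrom": chroms, "bp": pos})
    if fam_path is not None:
        fam = pd.read_csv(fam_path, sep="\t", dtype={"id": str})
        fam_map = dict(zip(fam["id"].astype(str), fam["family"]))
        family = np.asarray([fam_map[str(i)] for i in ids])
    else:
        family = np.zeros(len(ids), dtype=int)
    return MarkerPanel(
        genotypes=g,
        marker_ids=np.asarray(markers, dtype=object),
        map=GeneticMap(map_tbl),
        individual_ids=ids,
        family=family,
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a plot-level phenotype table (CSV dialect of the pipeline)."""
    df = pd.read_csv(path)
    required = {"id", "family", "env", "block", "row", "col", "is_check"}
    missing = required - set(df.columns)
    if missing:
        raise PanelValidationError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def impute_and_filter(panel: MarkerPanel, maf_min: float = 0.05) -> QCResult:
    """Impute missing calls by the within-family modal code, then MAF-filter.

    Missing calls are replaced by the most frequent code among observed
    calls of the same family at that marker; ties and all-missing families
    fall back to the global modal code.  Allele frequencies are computed
    on the imputed codes and markers with ``min(p, 1-p) < maf_min`` are
    removed.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    g = panel.genotypes.copy()
    n_imputed = 0
    if panel.has_missing:
        # counts[f, c, j]: occurrences of code c within family f at marker j
        fams, fam_idx = np.unique(panel.family, return_inverse=True)
        counts = np.zeros((len(fams), 3, g.shape[1]), dtype=np.int32)
        for c in (0, 1, 2):
            hits = (g == c)
            for f in range(len(fams)):
                counts[f, c] = hits[fam_idx == f].sum(axis=0)
        global_counts = counts.sum(axis=0)  # 3 x m
        global_mode = np.argmax(global_counts, axis=0).astype(np.int8)
        fam_mode = np.argmax(counts, axis=1).astype(np.int8)  # families x m
        # ties (top count shared by >1 code) and all-missing -> global mode
        top = np.take_along_axis(counts, fam_mode[:, None, :], axis=1)[:, 0, :]
        n_at_top = (counts == top[:, None, :]).sum(axis=1)
        use_global = (n_at_top > 1) | (top == 0)
        fill = np.where(use_global, global_mode[None, :], fam_mode)
        miss_i, miss_j = np.nonzero(g == MISSING)
        g[miss_i, miss_j] = fill[fam_idx[miss_i], miss_j]
        n_imputed = len(miss_i)
    p = g.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise PanelValidationError(
            f"no markers retained at MAF >= {maf_min}: panel is monomorphic or near-fixed"
        )
    out = replace(panel, genotypes=g).subset_markers(keep)
    return QCResult(
        panel=out,
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        n_imputed=n_imputed,
    )
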