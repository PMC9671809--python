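"""Layer containers, configuration and seeded-stream plumbing.

Every analysis stage consumes :class:`OmicsLayer` objects — named
sample x feature matrices tagged with the kind of data they hold — and a
:class:`RunConfig` carrying the thresholds the study design fixes (FDR
level, study-wide mQTL alpha, instrument rules, clumping parameters,
permutation counts and so on).  Matrices travel as tab-separated text:
first row feature ids, first column sample ids, ``NA`` for missing.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("metabvar")

__all__ = [
    "LayerKind",
    "OmicsLayer",
    "RunConfig",
    "read_layer",
    "write_layer",
    "stage_rng",
]


class LayerKind(str, Enum):
    METABOLOME = "metabolome"
    GENOTYPE = "genotype"
    MICROBIOME_TAXA = "microbiome_taxa"
    MICROBIOME_PATHWAY = "microbiome_pathway"
    DIET = "diet"
    COVARIATES = "covariates"


@dataclass
class OmicsLayer:
    """A validated sample x feature numeric matrix.

    Parameters
    ----------
    kind : LayerKind
        What the values are (metabolite intensities, genotype dosages in
        [0, 2], microbiome relative abundances in [0, 1], dietary-habit
        scores, or covariates).
    data : pandas.DataFrame
        Samples in rows, features in columns.
    feature_meta : pandas.DataFrame, optional
        Per-feature metadata indexed like ``data.columns``; for genotypes
        this holds ``chrom``, ``pos`` (1-based bp) and ``effect_allele``.
    """

    kind: LayerKind
    data: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    transformed: bool = False  # True once values left their raw scale (e.g. CLR)

    def __post_init__(self) -> None:
        self.kind = LayerKind(self.kind)
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature id(s): {dup}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = self.data.columns[
                [not np.issubdtype(d, np.number) for d in self.data.dtypes]
            ].tolist()
            raise ValueError(f"non-numeric column(s): {bad}")
        finite = vals[~np.isnan(vals)]
        if not self.transformed and finite.size:
            if self.kind is LayerKind.GENOTYPE and (finite.min() < 0 or finite.max() > 2):
                raise ValueError("genotype dosages must lie within [0, 2]")
            if self.kind in (LayerKind.MICROBIOME_TAXA, LayerKind.MICROBIOME_PATHWAY) and (
                finite.min() < 0 or finite.max() > 1 + 1e-9
            ):
                raise ValueError("relative abundances must lie within [0, 1]")
        if self.feature_meta is not None:
            missing = self.data.columns.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(f"feature_meta missing entries for: {missing.tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, transformed: bool | None = None) -> "OmicsLayer":
        meta = self.feature_meta
        if meta is not None:
            meta = meta.loc[meta.index.intersection(data.columns)]
        t = self.transformed if transformed is None else transformed
        return OmicsLayer(self.kind, data, meta, transformed=t)


DEFAULT_THRESHOLDS: dict[str, float] = {
    "fdr_level": 0.05,
    "mqtl_alpha": 5.0e-8,
    "n_metabolite_tests": 0,  # 0 -> use the metabolome layer width
    "instrument_p": 1e-5,
    "min_instruments": 3,
    "clump_r2": 0.05,
    "clump_window_bp": 500_000,
    "permanova_permutations": 1000,
    "dissimilarity_cut": 0.70,
    "prevalence_min": 0.10,
    "cv_folds": 10,
    "mediation_sims": 1000,
}


@dataclass
class RunConfig:
    """Run-level settings shared by every stage."""

    seed: int = 0
    covariate_names: list[str] = field(default_factory=lambda: ["age", "sex", "smoking"])
    thresholds: dict[str, float] = field(default_factory=dict)
    regularization_mode: str = "lasso"  # or "elastic_net"

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if self.regularization_mode not in ("lasso", "elastic_net"):
            raise ValueError(f"unknown regularization_mode: {self.regularization_mode}")
        for key, val in self.thresholds.items():
            if key == "n_metabolite_tests":
                continue
            if val <= 0:
                raise ValueError(f"threshold {key} must be positive, got {val}")
        for key in ("fdr_level", "dissimilarity_cut"):
            if not 0 < self.thresholds[key] < 1:
                raise ValueError(f"{key} must be in (0, 1)")

    def threshold(self, name: str) -> float:
        return self.thresholds[name]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            covariate_names=list(raw.get("covariate_names", ["age", "sex", "smoking"])),
            thresholds=dict(raw.get("thresholds", {})),
            regularization_mode=raw.get("regularization_mode", "lasso"),
        )

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator stream for one named stage.

    Keyed by (global seed, CRC32 of the stage name) so that adding or
    reordering stages never perturbs another stage's draws.
    """
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


def read_layer(path: str | Path, kind: LayerKind | str) -> OmicsLayer:
    """Read a tab-separated sample x feature table as an :class:`OmicsLayer`.

    First row holds feature ids, first column sample ids, the body is
    numeric with ``NA`` for missing.  Duplicate ids, dimension mismatches
    and non-numeric cells are rejected with a message locating the problem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])
    dup_s = df.index[df.index.duplicated()].unique().tolist()
    if dup_s:
        raise ValueError(f"{path}: duplicate sample id(s): {dup_s}")
    dup_f = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_f:
        raise ValueError(f"{path}: duplicate feature id(s): {dup_f}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric cell(s) in feature {col!r}"
                + (f" at sample(s) {bad.tolist()[:5]}" if len(bad) else "")
            )
    n_na = int(df.isna().to_numpy().sum())
    if n_na:
        log.info("read_layer(%s): %d missing values", path.name, n_na)
    return OmicsLayer(LayerKind(kind), df.astype(float))


def write_layer(layer: OmicsLayer, path: str | Path, header: Mapping[str, object] | None = None) -> None:
    """Write a layer as TSV at 12 significant digits, with optional
    ``# key=value`` provenance comment lines before the header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"# {k}={v}\n")
        layer.data.to_csv(fh, sep="\t", float_format="%.12g", na_rep="NA")


def write_table(df: pd.DataFrame, path: str | Path, header: Mapping[str, object] | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV with provenance comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            for k, v in header.items():
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", float_format="%.12g", na_rep="NA", index=index)


def align_samples(*layers: OmicsLayer | pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict a set of layers/frames to their shared samples, in the
    order of the first argument. Raises if the intersection is empty."""
    frames = [l.data if isinstance(l, OmicsLayer) else l for l in layers]
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between layers")
    common = [s for s in frames[0].index if s in set(common)]
    return [f.loc[common] for f in frames]
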