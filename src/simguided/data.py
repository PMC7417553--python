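"""Multimodal dataset model, manifest I/O, and missingness bookkeeping.

A cohort is a tree of modalities -> submodalities -> features (the unit at
which models are fitted is the submodality), plus per-subject outcomes
(binary label and/or continuous response) and conventional covariates
(sex, age, cohort, handedness).  Feature tables are CSV, one per
submodality, joined on a mandatory ``subject_id`` column; missing cells are
empty (or the token ``NaN``) and are tracked as an explicit boolean mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetLayout",
    "MultimodalDataset",
    "MissingMask",
    "SubmodalityBlock",
    "load_dataset",
    "write_dataset",
    "extract_missing_mask",
    "split_into_submodalities",
    "one_hot_covariates",
]

#: covariate columns expected in every covariates table
COVARIATE_COLUMNS = ("sex", "age", "cohort", "handedness")
#: covariates that are categorical and one-hot encoded at load time
CATEGORICAL_COVARIATES = ("sex", "cohort", "handedness")


@dataclass(frozen=True)
class DatasetLayout:
    """The modality -> submodality -> feature tree plus the subject count.

    Parameters
    ----------
    modalities
        Mapping from modality name to an ordered mapping of submodality
        name -> tuple of feature names.
    n_subjects
        Number of subjects every block must have.
    """

    modalities: Mapping[str, Mapping[str, tuple[str, ...]]]
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        seen: set[str] = set()
        for mod, subs in self.modalities.items():
            if not subs:
                raise ValueError(f"modality {mod!r} has no submodalities")
            for sub, feats in subs.items():
                if len(feats) == 0:
                    raise ValueError(f"submodality {sub!r} has no features")
                for f in feats:
                    if f in seen:
                        raise ValueError(f"duplicate feature name {f!r}")
                    seen.add(f)

    @property
    def modality_names(self) -> list[str]:
        return list(self.modalities)

    @property
    def submodality_names(self) -> list[str]:
        return [s for subs in self.modalities.values() for s in subs]

    def features_of(self, submodality: str) -> tuple[str, ...]:
        for subs in self.modalities.values():
            if submodality in subs:
                return tuple(subs[submodality])
        raise KeyError(submodality)

    @property
    def feature_names(self) -> list[str]:
        return [f for subs in self.modalities.values() for fs in subs.values() for f in fs]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dict(self) -> dict:
        return {
            "modalities": {
                mod: {sub: list(feats) for sub, feats in subs.items()}
                for mod, subs in self.modalities.items()
            },
            "n_subjects": self.n_subjects,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetLayout":
        mods = {
            mod: {sub: tuple(feats) for sub, feats in subs.items()}
            for mod, subs in d["modalities"].items()
        }
        return cls(modalities=mods, n_subjects=int(d["n_subjects"]))


@dataclass
class MissingMask:
    """Per-submodality boolean missingness (True = missing)."""

    blocks: dict[str, pd.DataFrame]

    @property
    def fractions(self) -> dict[str, float]:
        """Missing fraction per block, in [0, 1]."""
        return {name: float(m.to_numpy().mean()) for name, m in self.blocks.items()}

    def block_rows_missing(self, name: str) -> np.ndarray:
        """Boolean vector: subject's entire block is missing."""
        return self.blocks[name].to_numpy().all(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MissingMask):
            return NotImplemented
        if set(self.blocks) != set(other.blocks):
            return False
        return all(self.blocks[k].equals(other.blocks[k]) for k in self.blocks)


@dataclass
class MultimodalDataset:
    """Per-submodality feature blocks with mask, outcomes and covariates.

    ``blocks`` maps submodality name -> DataFrame (subjects x features,
    indexed by subject id) with NaN marking missing entries.  ``outcomes``
    has columns ``label`` (binary, may be absent) and ``response``
    (continuous, may be absent).  ``covariates`` is fully numeric
    (categoricals one-hot encoded).
    """

    layout: DatasetLayout
    blocks: dict[str, pd.DataFrame]
    outcomes: pd.DataFrame
    covariates: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.subject_ids
        for name, block in self.blocks.items():
            if len(block) != self.layout.n_subjects:
                raise ValueError(
                    f"block {name!r} has {len(block)} subjects, layout says "
                    f"{self.layout.n_subjects}"
                )
            if not block.index.equals(ids):
                raise ValueError(f"block {name!r} subject order differs from outcomes")
            expected = list(self.layout.features_of(name))
            if list(block.columns) != expected:
                raise ValueError(
                    f"block {name!r} columns {list(block.columns)} do not match "
                    f"layout features {expected}"
                )

    @property
    def subject_ids(self) -> pd.Index:
        return self.outcomes.index

    @property
    def n_subjects(self) -> int:
        return self.layout.n_subjects

    @property
    def labels(self) -> np.ndarray | None:
        if "label" not in self.outcomes or self.outcomes["label"].isna().all():
            return None
        return self.outcomes["label"].to_numpy(dtype=float)

    @property
    def response(self) -> np.ndarray | None:
        if "response" not in self.outcomes or self.outcomes["response"].isna().all():
            return None
        return self.outcomes["response"].to_numpy(dtype=float)

    def full_matrix(self) -> pd.DataFrame:
        """All feature blocks concatenated in layout order (no covariates)."""
        return pd.concat([self.blocks[s] for s in self.layout.submodality_names], axis=1)


@dataclass
class SubmodalityBlock:
    """One submodality ready for fitting: features + appended covariates.

    ``available`` flags subjects with at least one observed feature in this
    block; subjects with the entire block missing contribute no prediction
    from it under late integration.
    """

    name: str
    X: pd.DataFrame          # features then covariate columns
    mask: pd.DataFrame       # over the feature columns only
    n_features: int          # number of original (non-covariate) columns
    available: np.ndarray    # bool per subject

    @property
    def feature_columns(self) -> list[str]:
        return list(self.X.columns[: self.n_features])

    @property
    def covariate_columns(self) -> list[str]:
        return list(self.X.columns[self.n_features:])


def one_hot_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode categorical covariates, keep numeric ones as-is.

    Column order is stable: age first, then the dummies of each categorical
    covariate in sorted level order.
    """
    missing = [c for c in COVARIATE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"covariates table lacks columns {missing}")
    parts = [raw[["age"]].astype(float)]
    for col in CATEGORICAL_COVARIATES:
        levels = sorted(raw[col].astype(str).unique())
        for lv in levels:
            parts.append(
                (raw[col].astype(str) == lv).astype(float).rename(f"{col}_{lv}")
            )
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# manifest I/O

def _read_table(path: Path, required: Sequence[str], what: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{what}: file {path} does not exist")
    df = pd.read_csv(path, na_values=["NaN"], keep_default_na=True)
    if "subject_id" not in df.columns:
        raise ValueError(f"{what}: {path} lacks a subject_id column")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{what}: duplicated subject id {dup!r} in {path}")
    lacking = [c for c in required if c not in df.columns]
    if lacking:
        raise ValueError(f"{what}: {path} lacks declared column(s) {lacking}")
    return df.set_index("subject_id")


def load_dataset(manifest_path: str | Path) -> MultimodalDataset:
    """Load a dataset described by a JSON manifest.

    The manifest has keys ``layout``, ``blocks`` (submodality -> CSV path,
    relative to the manifest), ``outcomes``, ``covariates`` and ``meta``.
    All tables are joined on ``subject_id``; the subject order of the
    outcomes table is canonical.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    layout = DatasetLayout.from_dict(manifest["layout"])

    outcomes = _read_table(root / manifest["outcomes"], [], "outcomes")
    if len(outcomes) != layout.n_subjects:
        raise ValueError(
            f"outcomes table has {len(outcomes)} subjects, layout says "
            f"{layout.n_subjects}"
        )
    ids = outcomes.index

    raw_cov = _read_table(root / manifest["covariates"], list(COVARIATE_COLUMNS),
                          "covariates")
    covariates = one_hot_covariates(raw_cov.loc[ids])

    blocks: dict[str, pd.DataFrame] = {}
    for sub in layout.submodality_names:
        if sub not in manifest["blocks"]:
            raise ValueError(f"manifest lacks a CSV for submodality {sub!r}")
        feats = list(layout.features_of(sub))
        df = _read_table(root / manifest["blocks"][sub], feats, f"block {sub!r}")
        extra = [c for c in df.columns if c not in feats]
        if extra:
            raise ValueError(f"block {sub!r}: undeclared column(s) {extra}")
        if not set(ids) <= set(df.index):
            lost = sorted(set(ids) - set(df.index))[:3]
            raise ValueError(f"block {sub!r}: missing subject id(s) {lost}")
        blocks[sub] = df.loc[ids, feats].astype(float)

    meta = dict(manifest.get("meta", {}))
    # keep the raw (pre-one-hot) covariates so the dataset can be re-written
    meta["_raw_covariates"] = raw_cov.loc[ids].reset_index().to_dict(
        orient="list")
    return MultimodalDataset(
        layout=layout,
        blocks=blocks,
        outcomes=outcomes,
        covariates=covariates,
        meta=meta,
    )


def write_dataset(dataset: MultimodalDataset, out_dir: str | Path,
                  name: str = "dataset") -> Path:
    """Write manifest + CSVs; returns the manifest path.

    Missing entries are emitted as empty cells.  ``load_dataset`` of the
    result reproduces values, mask and layout (covariates round-trip
    through the raw table stored in meta-free form).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks_entry = {}
    for sub, block in dataset.blocks.items():
        fname = f"{name}_{sub}.csv"
        block.to_csv(out_dir / fname, index_label="subject_id")
        blocks_entry[sub] = fname

    outcomes_name = f"{name}_outcomes.csv"
    dataset.outcomes.to_csv(out_dir / outcomes_name, index_label="subject_id")

    cov_name = f"{name}_covariates.csv"
    raw_cov = dataset.meta.get("_raw_covariates")
    if raw_cov is not None:
        pd.DataFrame(raw_cov).set_index("subject_id").loc[dataset.subject_ids].to_csv(
            out_dir / cov_name, index_label="subject_id")
    else:  # already-numeric covariates: store as-is with passthrough columns
        dataset.covariates.to_csv(out_dir / cov_name, index_label="subject_id")

    meta = {k: v for k, v in dataset.meta.items() if not k.startswith("_")}
    manifest = {
        "layout": dataset.layout.to_dict(),
        "blocks": blocks_entry,
        "outcomes": outcomes_name,
        "covariates": cov_name,
        "meta": meta,
    }
    manifest_path = out_dir / f"{name}.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def extract_missing_mask(dataset: MultimodalDataset) -> MissingMask:
    """Boolean mask per block, True exactly where an entry is missing."""
    return MissingMask(
        blocks={name: block.isna() for name, block in dataset.blocks.items()}
    )


def split_into_submodalities(dataset: MultimodalDataset) -> list[SubmodalityBlock]:
    """Split into per-submodality blocks with covariates appended.

    Covariates are appended as extra columns to every block so each
    submodality model is self-contained under late integration.
    Concatenating the feature parts in layout order reconstructs the full
    feature matrix.
    """
    out = []
    for sub in dataset.layout.submodality_names:
        block = dataset.blocks[sub]
        mask = block.isna()
        available = ~mask.to_numpy().all(axis=1)
        X = pd.concat([block, dataset.covariates], axis=1)
        out.append(SubmodalityBlock(
            name=sub, X=X, mask=mask, n_features=block.shape[1],
            available=available,
        ))
    return out


def iter_blocks(dataset: MultimodalDataset) -> Iterator[tuple[str, pd.DataFrame]]:
    for sub in dataset.layout.submodality_names:
        yield sub, dataset.blocks[sub]
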