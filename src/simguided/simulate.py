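"""Latent-variable cohort simulator with dB-scale SNR control.

Each subject carries a one-dimensional latent trait z that drives every
feature and the outcome.  Two restrictions embody the two standing
hypotheses about treatment response: a *cluster* trait (two discrete
subgroups, z in {-1, +1}) and a *spectrum* trait (a continuum, z standard
normal).  Features are z times a frozen loading plus Gaussian noise; the
noise is rescaled after the fact so the realized dataset-level
Var(signal)/Var(noise) hits 10**(snr_db/10) exactly.  Missingness patterns
extracted from a real cohort (or a reference stand-in) are grafted onto
the simulated data so simulated and real analyses face the same holes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .data import (
    DatasetLayout,
    MissingMask,
    MultimodalDataset,
    one_hot_covariates,
)

__all__ = [
    "LatentCohortSpec",
    "GridSpec",
    "LoadingModel",
    "sample_latent",
    "derive_outcomes",
    "generate_cohort",
    "apply_missing_pattern",
    "build_grid",
    "reference_fixture",
    "reference_layout",
    "small_layout",
    "random_loadings",
    "stage_seed",
    "DEFAULT_SNR_GRID_DB",
]

Variant = Literal["cluster", "spectrum"]
OutcomeLink = Literal["binary_threshold", "cluster_label", "linear_response"]

#: the default SNR sweep: -20 to +20 dB in steps of 5
DEFAULT_SNR_GRID_DB: tuple[float, ...] = tuple(float(s) for s in range(-20, 25, 5))


def stage_seed(master: int, *parts) -> int:
    """Deterministic per-stage seed derived from a master seed.

    Hashes the master seed together with stage labels/indices so that
    replications are independent yet reproducible; result is below 2**31.
    """
    key = ":".join([str(master), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class LatentCohortSpec:
    """Parameters of one simulated cohort."""

    layout: DatasetLayout
    variant: Variant = "cluster"
    snr_db: float = 0.0
    outcome_link: OutcomeLink = "cluster_label"
    mixing_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.variant not in ("cluster", "spectrum"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "cluster" and not 0.0 < self.mixing_proportion < 1.0:
            raise ValueError("mixing_proportion must lie in (0, 1)")

    @property
    def n_subjects(self) -> int:
        return self.layout.n_subjects


@dataclass(frozen=True)
class LoadingModel:
    """Per-submodality loading vectors w and per-feature noise scales."""

    loadings: dict[str, np.ndarray]     # submodality -> (n_features,)
    noise_scale: dict[str, np.ndarray]  # submodality -> (n_features,), > 0

    def __post_init__(self) -> None:
        for sub, w in self.loadings.items():
            if not np.any(w != 0):
                raise ValueError(f"all-zero loadings in submodality {sub!r}")
            if np.any(self.noise_scale[sub] <= 0):
                raise ValueError(f"non-positive noise scale in {sub!r}")


@dataclass(frozen=True)
class GridSpec:
    """The simulation grid: SNR sweep x latent variants x seeds."""

    base: LatentCohortSpec
    snr_values: tuple[float, ...] = DEFAULT_SNR_GRID_DB
    variants: tuple[Variant, ...] = ("cluster", "spectrum")
    seeds: tuple[int, ...] = tuple(range(10))

    def __post_init__(self) -> None:
        if not (self.snr_values and self.variants and self.seeds):
            raise ValueError("snr_values, variants and seeds must be non-empty")

    @property
    def size(self) -> int:
        return len(self.snr_values) * len(self.variants) * len(self.seeds)

    def cells(self) -> Iterable[LatentCohortSpec]:
        for snr in self.snr_values:
            for variant in self.variants:
                for seed in self.seeds:
                    yield replace(self.base, snr_db=snr, variant=variant, seed=seed)


def sample_latent(spec: LatentCohortSpec) -> np.ndarray:
    """Draw the latent trait vector z, deterministically given the seed.

    Cluster variant: z_i in {-1, +1} with P(+1) = mixing_proportion.
    Spectrum variant: z_i ~ N(0, 1).
    """
    n = spec.n_subjects
    if n <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(stage_seed(spec.seed, "latent", spec.variant))
    if spec.variant == "cluster":
        return np.where(rng.random(n) < spec.mixing_proportion, 1.0, -1.0)
    return rng.standard_normal(n)


def derive_outcomes(z: np.ndarray, link: OutcomeLink, seed: int,
                    snr_db: float = 0.0) -> pd.DataFrame:
    """Attach outcomes to a latent vector.

    cluster_label:    label = 1(z > 0)
    binary_threshold: label = 1(z > median(z))        (strict inequality)
    linear_response:  response = z + noise, noise variance set so that
                      Var(z)/Var(noise) = 10**(snr_db/10)
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("latent vector is empty")
    out = pd.DataFrame(index=pd.RangeIndex(z.size))
    if link == "cluster_label":
        out["label"] = (z > 0).astype(int)
    elif link == "binary_threshold":
        out["label"] = (z > np.median(z)).astype(int)
    elif link == "linear_response":
        rng = np.random.default_rng(stage_seed(seed, "outcome_noise"))
        snr = 10.0 ** (snr_db / 10.0)
        noise = rng.standard_normal(z.size)
        noise *= np.sqrt(np.var(z) / (snr * np.var(noise)))
        out["response"] = z + noise
    else:
        raise ValueError(f"unknown outcome link {link!r}")
    return out


def random_loadings(layout: DatasetLayout, seed: int) -> LoadingModel:
    """Standard-normal loadings drawn once and frozen; unit noise scales."""
    rng = np.random.default_rng(stage_seed(seed, "loadings"))
    loadings, scales = {}, {}
    for sub in layout.submodality_names:
        p = len(layout.features_of(sub))
        w = rng.standard_normal(p)
        while not np.any(w != 0):  # pragma: no cover - measure-zero event
            w = rng.standard_normal(p)
        loadings[sub] = w
        scales[sub] = np.ones(p)
    return LoadingModel(loadings=loadings, noise_scale=scales)


def _simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Sex/age/cohort/handedness resembling a first-episode psychosis cohort."""
    rng = np.random.default_rng(stage_seed(seed, "covariates"))
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "sex": rng.choice(["M", "F"], size=n, p=[0.66, 0.34]),
        "age": np.clip(rng.normal(25.4, 5.7, size=n), 18, 45).round(1),
        "cohort": rng.choice(["A", "B", "C"], size=n, p=[0.2, 0.34, 0.46]),
        "handedness": rng.choice(["R", "L", "A"], size=n, p=[0.88, 0.1, 0.02]),
    })


def generate_cohort(spec: LatentCohortSpec,
                    loadings: LoadingModel | None = None) -> MultimodalDataset:
    """Generate a fully observed multimodal cohort at the requested SNR.

    Each feature j is w_j * z_i + eps_ij with Gaussian noise; the noise
    matrix is rescaled post hoc so the realized dataset-level
    Var(signal)/Var(noise) equals 10**(snr_db/10) exactly.  Outcomes are
    attached via the spec's outcome link; holes are added separately by
    :func:`apply_missing_pattern`.
    """
    layout = spec.layout
    if loadings is None:
        loadings = random_loadings(layout, spec.seed)
    for sub in layout.submodality_names:
        if sub not in loadings.loadings:
            raise ValueError(f"loadings lack submodality {sub!r}")
        if len(loadings.loadings[sub]) != len(layout.features_of(sub)):
            raise ValueError(f"loadings shape mismatch in {sub!r}")

    z = sample_latent(spec)
    rng = np.random.default_rng(stage_seed(spec.seed, "noise", spec.variant,
                                           spec.snr_db))

    signal = {s: np.outer(z, loadings.loadings[s]) for s in layout.submodality_names}
    noise = {
        s: rng.standard_normal(signal[s].shape) * loadings.noise_scale[s]
        for s in layout.submodality_names
    }
    sig_var = np.var(np.concatenate([m.ravel() for m in signal.values()]))
    noi_var = np.var(np.concatenate([m.ravel() for m in noise.values()]))
    target = 10.0 ** (spec.snr_db / 10.0)
    scale = np.sqrt(sig_var / (target * noi_var))

    ids = pd.Index([f"S{i:04d}" for i in range(spec.n_subjects)], name="subject_id")
    blocks = {
        s: pd.DataFrame(signal[s] + scale * noise[s], index=ids,
                        columns=list(layout.features_of(s)))
        for s in layout.submodality_names
    }

    outcomes = derive_outcomes(z, spec.outcome_link, spec.seed, spec.snr_db)
    outcomes.index = ids

    raw_cov = _simulate_covariates(spec.n_subjects, spec.seed)
    covariates = one_hot_covariates(raw_cov.set_index("subject_id").set_axis(ids))

    return MultimodalDataset(
        layout=layout,
        blocks=blocks,
        outcomes=outcomes,
        covariates=covariates,
        meta={
            "variant": spec.variant,
            "snr_db": spec.snr_db,
            "seed": spec.seed,
            "outcome_link": spec.outcome_link,
            "latent": z.tolist(),
            "_raw_covariates": raw_cov.to_dict(orient="list"),
        },
    )


def apply_missing_pattern(dataset: MultimodalDataset, mask: MissingMask,
                          permute_subjects: bool = False,
                          seed: int = 0) -> MultimodalDataset:
    """Graft a missingness pattern onto a (typically simulated) dataset.

    Entry (i, j) becomes missing iff the mask is True there, after an
    optional row permutation.  When the mask was extracted from a cohort of
    a different size, rows are resampled with replacement (seeded);
    identity mapping when sizes match and no permutation is requested.
    Per-block missing fractions of the result equal the mask's exactly
    (up to row resampling).
    """
    n = dataset.n_subjects
    blocks: dict[str, pd.DataFrame] = {}
    row_map: np.ndarray | None = None
    for name in dataset.layout.submodality_names:
        if name not in mask.blocks:
            raise ValueError(f"mask lacks block {name!r}")
        m = mask.blocks[name].to_numpy()
        block = dataset.blocks[name]
        if m.shape[1] != block.shape[1]:
            raise ValueError(
                f"block {name!r}: mask has {m.shape[1]} features, data has "
                f"{block.shape[1]}"
            )
        if row_map is None:
            rng = np.random.default_rng(stage_seed(seed, "mask_rows"))
            if m.shape[0] == n:
                row_map = (rng.permutation(n) if permute_subjects
                           else np.arange(n))
            else:
                row_map = rng.integers(0, m.shape[0], size=n)
        mm = m[row_map]
        values = block.to_numpy(copy=True)
        values[mm] = np.nan
        blocks[name] = pd.DataFrame(values, index=block.index,
                                    columns=block.columns)
    out = MultimodalDataset(
        layout=dataset.layout, blocks=blocks, outcomes=dataset.outcomes.copy(),
        covariates=dataset.covariates.copy(), meta=dict(dataset.meta),
    )
    out.meta["missing_pattern_applied"] = True
    return out


def build_grid(grid: GridSpec, loadings: LoadingModel | None = None,
               mask: MissingMask | None = None) -> list[MultimodalDataset]:
    """Materialize every grid cell; default grid yields 180 datasets."""
    out = []
    for spec in grid.cells():
        ds = generate_cohort(spec, loadings)
        if mask is not None:
            ds = apply_missing_pattern(ds, mask, seed=spec.seed)
        out.append(ds)
    return out


# ---------------------------------------------------------------------------
# reference layouts

_REFERENCE_TREE: dict[str, dict[str, int]] = {
    # modality -> submodality -> default feature count
    "cognition": {
        "DART": 1, "WAIS": 4, "CANTAB_SSP": 2, "CANTAB_SWM": 3,
        "CANTAB_SOC": 2, "CANTAB_IED": 2, "CANTAB_RVP": 2, "CANTAB_RTI": 2,
        "BACS": 6, "Buschke": 3, "SDMT": 1, "TMT": 2, "WCST": 3, "SCOLP": 2,
    },
    "MRI": {
        "cortical_thickness_lh": 4, "cortical_thickness_rh": 4,
        "surface_area_lh": 4, "surface_area_rh": 4,
        "mean_curvature_lh": 3, "mean_curvature_rh": 3,
        "subcortical_volumes": 6,
    },
    "electrophysiology": {"MMN": 4, "PPI": 4, "P50": 3, "SA": 3},
    "psychopathology": {
        "PANSS_positive": 2, "PANSS_negative": 2, "PANSS_general": 2,
    },
    "perinatal_register": {"birth": 4, "apgar": 2, "parental_age": 2},
}

#: blocks missing wholesale for a fraction of subjects (no session / no record)
_BLOCKWISE_MISSING: dict[str, float] = {
    "cortical_thickness_lh": 0.15, "cortical_thickness_rh": 0.15,
    "surface_area_lh": 0.15, "surface_area_rh": 0.15,
    "mean_curvature_lh": 0.18, "mean_curvature_rh": 0.18,
    "subcortical_volumes": 0.15,
    "MMN": 0.12, "PPI": 0.12, "P50": 0.14, "SA": 0.12,
    "birth": 0.2, "apgar": 0.22, "parental_age": 0.2,
    "WAIS": 0.1, "WCST": 0.25, "SCOLP": 0.25,
}


def reference_layout(n_subjects: int = 289) -> DatasetLayout:
    """The 5-modality reference tree (cohort-shaped; 289 = 138 + 151)."""
    mods = {
        mod: {sub: tuple(f"{sub}_f{i}" for i in range(k))
              for sub, k in subs.items()}
        for mod, subs in _REFERENCE_TREE.items()
    }
    return DatasetLayout(modalities=mods, n_subjects=n_subjects)


def small_layout(n_subjects: int = 120, n_submodalities: int = 4,
                 n_features: int = 3) -> DatasetLayout:
    """A compact layout for fast benchmarking experiments."""
    names = ["cognition", "MRI", "electrophysiology", "psychopathology",
             "perinatal_register"]
    mods: dict[str, dict[str, tuple[str, ...]]] = {}
    for i in range(n_submodalities):
        mod = names[i % len(names)]
        sub = f"{mod}_block{i}"
        mods.setdefault(mod, {})[sub] = tuple(
            f"{sub}_f{j}" for j in range(n_features))
    return DatasetLayout(modalities=mods, n_subjects=n_subjects)


def reference_fixture(seed: int = 0, n_subjects: int = 289,
                      random_missing: float = 0.05,
                      ) -> tuple[DatasetLayout, MissingMask, LoadingModel]:
    """Layout, missingness mask and loadings mirroring the real cohort's shape.

    The mask combines block-wise holes (whole submodality absent for a
    subject, e.g. no MRI session or no register record) with ~5% randomly
    missing cells; deterministic given the seed.
    """
    layout = reference_layout(n_subjects)
    rng = np.random.default_rng(stage_seed(seed, "fixture_mask"))
    ids = pd.Index([f"S{i:04d}" for i in range(n_subjects)], name="subject_id")
    mask_blocks = {}
    for sub in layout.submodality_names:
        p = len(layout.features_of(sub))
        m = rng.random((n_subjects, p)) < random_missing
        frac = _BLOCKWISE_MISSING.get(sub, 0.0)
        if frac > 0:
            rows = rng.random(n_subjects) < frac
            m[rows] = True
        mask_blocks[sub] = pd.DataFrame(
            m, index=ids, columns=list(layout.features_of(sub)))
    loadings = random_loadings(layout, seed)
    return layout, MissingMask(blocks=mask_blocks), loadings
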