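"""Synthetic FR/UFR assay datasets with published multivariate structure.

The raw 98-sample measurements are not public; this module draws per-class
multivariate Gaussian samples whose marginal means come verbatim from the
published summary table, whose standard deviations are reconstructed from
the printed min–max ranges (σ = range / 4.5, the expected range of ~50
standard-normal draws), and whose within-solvent correlations come from the
published signed squared correlations via ρ = sign(v)·√|v|. Cross-solvent
correlations are zero, matching the reported absence of association between
the water and methanol measurements of the same assay.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .data import FR, UFR, FEATURE_COLUMNS, AssayDataset, SampleMeasurements

logger = logging.getLogger(__name__)

#: Expected range of ~50 iid normal draws, in units of σ.
RANGE_TO_SD = 4.5

#: Smallest eigenvalue allowed after correlation-matrix repair.
_EIG_FLOOR = 1e-8

#: Per-class seed offsets keep the FR and UFR streams independent.
_CLASS_SEED_OFFSET = {FR: 1, UFR: 2}

_MAX_REDRAWS = 100

# Published per-class summary statistics, in feature order
# (tpc_water, teac_water, frap_water, tpc_meoh, teac_meoh, frap_meoh).
_TABLE_MEAN = {
    FR: (278.89, 2871.18, 647.50, 256.815, 1965.38, 622.654),
    UFR: (282.08, 2443.58, 538.78, 302.66, 2421.41, 899.17),
}
_TABLE_MIN = {
    FR: (174.04, 1904.19, 360.61, 190.16, 1210.58, 460.310),
    UFR: (179.04, 1672.29, 338.90, 208.46, 1826.69, 585.304),
}
_TABLE_MAX = {
    FR: (558.41, 5133.38, 1306.71, 300.242, 2260.94, 925.56),
    UFR: (433.09, 3549.76, 949.89, 414.29, 2821.88, 1473.89),
}
# Published signed squared correlations for (TPC,TEAC), (TPC,FRAP),
# (TEAC,FRAP) within each solvent block.
_TABLE_SIGNED_R2 = {
    (FR, "water"): (0.919, 0.934, 0.928),
    (FR, "methanol"): (0.691, 0.212, -0.012),
    (UFR, "water"): (0.973, 0.929, 0.922),
    (UFR, "methanol"): (0.219, 0.116, 0.708),
}
_CLASS_N = {FR: 51, UFR: 47}


@dataclass(frozen=True)
class ClassGenParams:
    """Gaussian parameters for one fermentation class."""

    label: Literal["FR", "UFR"]
    n: int
    mean: np.ndarray  # 6-vector in feature order
    sd: np.ndarray  # 6-vector, strictly positive
    corr: np.ndarray  # 6x6 correlation matrix

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if self.mean.shape != (6,) or self.sd.shape != (6,):
            raise ValueError("mean and sd must be 6-vectors in feature order")
        if np.any(self.sd <= 0):
            raise ValueError("sd must be strictly positive")
        if self.corr.shape != (6, 6):
            raise ValueError("corr must be a 6x6 matrix")
        if not np.allclose(self.corr, self.corr.T, atol=1e-12):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-12):
            raise ValueError("corr must have a unit diagonal")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("corr entries must lie in [-1, 1]")

    def covariance(self) -> np.ndarray:
        """Σ = diag(sd) · corr · diag(sd) with the correlation repaired to PSD."""
        c = repair_correlation(self.corr)
        return np.outer(self.sd, self.sd) * c


@dataclass(frozen=True)
class GeneratorParams:
    """Full generator configuration: both classes plus the master seed."""

    fr: ClassGenParams
    ufr: ClassGenParams
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fr.label != FR or self.ufr.label != UFR:
            raise ValueError("fr.label must be 'FR' and ufr.label must be 'UFR'")

    def digest(self) -> str:
        payload = json.dumps(
            {
                lab: {
                    "n": p.n,
                    "mean": np.round(p.mean, 10).tolist(),
                    "sd": np.round(p.sd, 10).tolist(),
                    "corr": np.round(p.corr, 10).tolist(),
                }
                for lab, p in (("FR", self.fr), ("UFR", self.ufr))
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    # -- structured-text (YAML) round trip -------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        doc = {
            "seed": int(self.seed),
            "classes": {
                lab: {
                    "n": int(p.n),
                    "mean": p.mean.tolist(),
                    "sd": p.sd.tolist(),
                    "corr": p.corr.tolist(),
                }
                for lab, p in (("FR", self.fr), ("UFR", self.ufr))
            },
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorParams":
        doc = yaml.safe_load(Path(path).read_text())
        classes = {
            lab: ClassGenParams(
                label=lab,
                n=int(c["n"]),
                mean=np.asarray(c["mean"], dtype=float),
                sd=np.asarray(c["sd"], dtype=float),
                corr=np.asarray(c["corr"], dtype=float),
            )
            for lab, c in doc["classes"].items()
        }
        return cls(fr=classes["FR"], ufr=classes["UFR"], seed=int(doc.get("seed", 0)))


def _block_correlation(label: str) -> np.ndarray:
    """Assemble the 6x6 correlation: within-solvent blocks, zero across."""
    corr = np.eye(6)
    for solvent, offset in (("water", 0), ("methanol", 3)):
        v12, v13, v23 = _TABLE_SIGNED_R2[(label, solvent)]
        for (i, j), v in (((0, 1), v12), ((0, 2), v13), ((1, 2), v23)):
            rho = np.sign(v) * np.sqrt(abs(v))
            corr[offset + i, offset + j] = corr[offset + j, offset + i] = rho
    return corr


def default_paper_params(seed: int = 0) -> GeneratorParams:
    """Generator parameterization from the published summary tables.

    Means are the printed per-class averages; σ = (max − min) / 4.5 from the
    printed ranges; within-solvent ρ = sign(v)·√|v| from the printed signed
    squared correlations; cross-solvent correlations are zero; class sizes
    are the study's 51 FR and 47 UFR.
    """
    classes = {}
    for label in (FR, UFR):
        mean = np.asarray(_TABLE_MEAN[label], dtype=float)
        rng = np.asarray(_TABLE_MAX[label], dtype=float) - np.asarray(
            _TABLE_MIN[label], dtype=float
        )
        classes[label] = ClassGenParams(
            label=label,
            n=_CLASS_N[label],
            mean=mean,
            sd=rng / RANGE_TO_SD,
            corr=_block_correlation(label),
        )
    return GeneratorParams(fr=classes[FR], ufr=classes[UFR], seed=seed)


def repair_correlation(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric unit-diagonal matrix to the PSD correlation cone.

    Eigenvalues are clipped below at 1e-8 and the result rescaled back to a
    unit diagonal. An already-PSD input is returned unchanged (copy).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("corr must be symmetric")
    w, v = np.linalg.eigh(corr)
    if w.min() >= _EIG_FLOOR:
        return corr.copy()
    repaired = (v * np.clip(w, _EIG_FLOOR, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    change = np.abs(repaired - corr).max()
    logger.info("correlation repaired: max |Δentry| = %.3e", change)
    return repaired


def _gaussian_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor L with LLᵀ = cov, tolerant of semidefinite input."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_class_samples(
    params: ClassGenParams, seed: int
) -> list[SampleMeasurements]:
    """Draw ``params.n`` samples from N(mean, Σ), redrawing negative rows.

    Rows containing a negative value are redrawn from the same stream (not
    clipped) to keep the Gaussian shape intact; a sample exceeding 100
    redraws raises, surfacing pathological parameters. Deterministic given
    (params, seed).
    """
    rng = np.random.default_rng(seed)
    L = _gaussian_factor(params.covariance())
    n = params.n
    if n == 0:
        return []
    X = params.mean + rng.standard_normal((n, 6)) @ L.T
    redraws = np.zeros(n, dtype=int)
    bad = np.flatnonzero((X < 0).any(axis=1))
    while bad.size:
        redraws[bad] += 1
        if redraws.max() > _MAX_REDRAWS:
            raise RuntimeError(
                f"negative-value redraw cap ({_MAX_REDRAWS}) exceeded for class "
                f"{params.label}; parameters place substantial mass below zero"
            )
        X[bad] = params.mean + rng.standard_normal((bad.size, 6)) @ L.T
        bad = bad[(X[bad] < 0).any(axis=1)]
    return [
        SampleMeasurements(
            sample_id=f"{params.label}-{i + 1:04d}",
            label=params.label,
            **dict(zip(FEATURE_COLUMNS, map(float, row))),
        )
        for i, row in enumerate(X)
    ]


def class_seed(master_seed: int, label: str) -> int:
    """Per-class stream seed: master seed plus a fixed class offset."""
    return (int(master_seed) + _CLASS_SEED_OFFSET[label]) % (2**31)


def generate_dataset(params: GeneratorParams) -> AssayDataset:
    """FR samples then UFR samples, with provenance recording seed + digest."""
    fr = generate_class_samples(params.fr, class_seed(params.seed, FR))
    ufr = generate_class_samples(params.ufr, class_seed(params.seed, UFR))
    return AssayDataset(
        tuple(fr + ufr),
        provenance=f"synthetic seed={params.seed} params={params.digest()}",
    )


def with_sizes(params: GeneratorParams, n_fr: int, n_ufr: int) -> GeneratorParams:
    """Copy of ``params`` with the per-class sample counts replaced."""
    return GeneratorParams(
        fr=replace(params.fr, n=n_fr),
        ufr=replace(params.ufr, n=n_ufr),
        seed=params.seed,
    )
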