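"""Seeded synthetic descriptor datasets with known ground-truth dose models.

The generator emulates the *statistical shape* of the real 31-compound
descriptor table -- heavy-tailed positive laws for the half-life,
solubility and mass columns, a U-shaped bounded law for the
biodegradation probability, symmetric laws for lipophilicity and the log
biotransformation half-life -- and produces MRTD targets from a known
model plus Gaussian noise.  It makes no attempt to simulate chemistry:
descriptor values are statistical stand-ins, not computed from
structures.

Marginal laws are moment-matched (mean, SD) to the training-table footer
of the real dataset.  Descriptors are drawn independently by default
(matching the reported absence of multicollinearity); an equicorrelation
knob through a Gaussian copula exists for stress tests.

Determinism: one :class:`numpy.random.Generator` seeded from
``cfg.seed`` drives descriptor draws first and then a standard-normal
noise vector that is scaled by ``noise_sd``.  Identical seeds therefore
give identical descriptors and, across different ``noise_sd`` values,
identical underlying noise shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DESCRIPTOR_COLUMNS, validate_dataset
from .linear import published_mlr

#: family -> (mean, sd) targets taken from the real training table footer.
DEFAULT_DESCRIPTOR_LAWS: dict[str, tuple[str, float, float]] = {
    "oxid_hl": ("lognormal", 0.672, 2.769),
    "p_bd": ("beta", 0.402, 0.394),
    "log_bio_hl": ("normal", -2.5133, 1.5738),
    "alogp": ("normal", 0.939, 2.809),
    "asol": ("lognormal", 6.15, 10.90),
    "mw": ("lognormal", 362.72, 178.20),
}


@dataclass
class GeneratorConfig:
    """Conditions for one synthetic dataset.

    Parameters
    ----------
    n : int
        Number of compounds (default 31, the size of the real table).
    descriptor_laws : mapping
        Per-descriptor ``(family, mean, sd)``; families are ``lognormal``
        (positive, heavy-tailed), ``beta`` (bounded on [0, 1]) and
        ``normal``, each moment-matched to the given mean/SD.
    truth : model
        Any object with a ``predict`` accepting a dataset frame; defaults
        to the published MLR equation.
    noise_sd : float
        SD of the additive Gaussian dose noise, mg/kg/day.  The default,
        30, is of the order of the residual SD of the linear model on the
        real table.
    seed : int
        RNG seed; identical seeds give byte-identical datasets.
    clip_floor : float
        Minimum MRTD (mg/kg/day).  Doses are floored here so every
        generated record satisfies the dataset invariants; this is a
        generator artifact, not a property of real dose data.
    correlation : float
        Equicorrelation of the Gaussian copula coupling the descriptor
        draws; 0 (the default) draws them independently.
    train_fraction : float
        Fraction of records tagged ``train`` (the rest are ``test``);
        the default mirrors the real 23/8 split.
    """

    n: int = 31
    descriptor_laws: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_LAWS)
    )
    truth: object = None
    noise_sd: float = 30.0
    seed: int = 0
    clip_floor: float = 0.01
    correlation: float = 0.0
    train_fraction: float = 23 / 31

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -0.1 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [-0.1, 1)")
        if self.truth is None:
            self.truth = published_mlr()
        if not hasattr(self.truth, "predict"):
            raise ValueError("truth model must expose a predict method")


def _marginal(family: str, mean: float, sd: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF transform of uniforms into the moment-matched law."""
    if family == "normal":
        return stats.norm.ppf(u, loc=mean, scale=sd)
    if family == "lognormal":
        if mean <= 0:
            raise ValueError("lognormal mean must be positive")
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        return np.exp(stats.norm.ppf(u, loc=mu, scale=np.sqrt(s2)))
    if family == "beta":
        var = sd**2
        limit = mean * (1 - mean)
        if not 0 < var < limit:
            raise ValueError("beta sd incompatible with mean")
        nu = limit / var - 1
        return stats.beta.ppf(u, mean * nu, (1 - mean) * nu)
    raise ValueError(f"unknown distribution family {family!r}")


def generate(cfg: GeneratorConfig) -> tuple[pd.DataFrame, object]:
    """Draw a synthetic dataset; returns ``(dataset, truth_model)``."""
    missing = set(DESCRIPTOR_COLUMNS) - set(cfg.descriptor_laws)
    if missing:
        raise ValueError(f"descriptor_laws missing {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed)

    k = len(DESCRIPTOR_COLUMNS)
    z = rng.standard_normal((cfg.n, k))
    if cfg.correlation:
        rho = cfg.correlation
        shared = rng.standard_normal((cfg.n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z
    u = stats.norm.cdf(z)
    # keep the uniforms strictly inside (0, 1) for the ppf transforms
    u = np.clip(u, 1e-12, 1 - 1e-12)

    ds = pd.DataFrame({"name": [f"synthetic-{i + 1:04d}" for i in range(cfg.n)]})
    n_train = int(round(cfg.train_fraction * cfg.n))
    ds["subset"] = ["train"] * n_train + ["test"] * (cfg.n - n_train)
    for j, col in enumerate(DESCRIPTOR_COLUMNS):
        family, mean, sd = cfg.descriptor_laws[col]
        ds[col] = _marginal(family, mean, sd, u[:, j])

    noise_shape = rng.standard_normal(cfg.n)
    mrtd = np.asarray(cfg.truth.predict(ds), dtype=float) + cfg.noise_sd * noise_shape
    ds["mrtd"] = np.maximum(mrtd, cfg.clip_floor)
    ds = ds[["name", "subset", "mrtd", *DESCRIPTOR_COLUMNS]]
    validate_dataset(ds)
    return ds, cfg.truth
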