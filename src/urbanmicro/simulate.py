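"""Synthetic urban-microbiome data with planted ground truth.

Emulates the statistical structure the analysis assumes: per-sample library
sizes are log-normal; each OTU's counts follow one of the four count models
(Poisson, NB as an exact Poisson-gamma mixture, ZIP/ZINB as a zero point
mass mixed in) with mean ``N_i * exp(base + effect)``, where planted
city-year effects define the differential ground truth.  City covariates
are drawn uniformly in configurable ranges and compositional triplets come
from the Dirichlet regression model itself.

Random streams are split hierarchically (one child stream per OTU) so
adding OTUs does not perturb existing draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import AbundanceTable, CityCovariates, SampleMetadata
from .dirichlet import predict_means, simulate_dirichlet

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study-shaped defaults at reduced scale: 16 city-year groups of 10
    samples, 500 OTUs, log-normal library sizes with median 3e6 reads."""

    n_cities: int = 16
    years_per_city: int = 1
    samples_per_group: int = 10
    n_otus: int = 500
    library_log_mean: float = np.log(3e6)
    library_log_sd: float = 0.5
    #: per-OTU generator family and parameters
    model: str = "NB"
    base_rate_range: tuple[float, float] = (1e-6, 1e-4)  # counts per sequenced read
    dispersion: float = 0.5
    zero_inflation: float = 0.0
    #: mapping otu index -> (affected (city, year) groups, log-fold-change)
    planted: dict[int, tuple[tuple[tuple[str, str], ...], float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("P", "NB", "ZIP", "ZINB"):
            raise ValueError(f"unknown generator model {self.model!r}")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.base_rate_range
        if lo <= 0 or hi < lo:
            raise ValueError("base_rate_range must be positive and ordered")
        for otu, (groups, lfc) in self.planted.items():
            if not np.isfinite(lfc):
                raise ValueError(f"non-finite log-fold-change for OTU {otu}")

    def group_names(self) -> list[tuple[str, str]]:
        cities = [f"city{i:02d}" for i in range(self.n_cities)]
        years = [str(2016 + t) for t in range(self.years_per_city)]
        return [(c, y) for c in cities for y in years]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated dataset."""

    differential: dict[str, tuple[tuple[tuple[str, str], ...], float]]
    expected_rates: pd.DataFrame  # OTU x sample expected mean counts
    dirichlet_coefficients: Optional[dict] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "otu_id": otu,
                "log_fold_change": lfc,
                "affected_groups": ";".join(f"{c}-{y}" for c, y in groups),
            }
            for otu, (groups, lfc) in sorted(self.differential.items())
        ]
        return pd.DataFrame(rows, columns=["otu_id", "log_fold_change", "affected_groups"])


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, model: str,
                 phi: float, pi: float) -> np.ndarray:
    """Counts with mean mu under the requested family.

    NB is drawn exactly as the Poisson-gamma mixture: the rate is multiplied
    by a Gamma(1/phi, 1/phi) frailty (mean 1, variance phi), then
    Poisson-sampled.  ZIP/ZINB replace a pi-fraction with structural zeros.
    """
    if model in ("NB", "ZINB") and phi > 0:
        frailty = rng.gamma(shape=1.0 / phi, scale=phi, size=mu.shape)
        lam = mu * frailty
    else:
        lam = mu
    counts = rng.poisson(lam)
    if model in ("ZIP", "ZINB") and pi > 0:
        counts = np.where(rng.random(mu.shape) < pi, 0, counts)
    return counts


def simulate_abundance(config: SimConfig) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Simulate (table, metadata, truth) under ``config``; bit-reproducible."""
    groups = config.group_names()
    sample_ids: list[str] = []
    sample_group: list[tuple[str, str]] = []
    for city, year in groups:
        for r in range(config.samples_per_group):
            sample_ids.append(f"{city}_{year}_s{r:02d}")
            sample_group.append((city, year))

    root = np.random.SeedSequence(config.seed)
    lib_seq, otu_root = root.spawn(2)
    lib_rng = np.random.default_rng(lib_seq)
    n = len(sample_ids)
    library = np.exp(lib_rng.normal(config.library_log_mean, config.library_log_sd, size=n))
    library = np.maximum(library.round().astype(np.int64), 1)

    otu_seqs = otu_root.spawn(config.n_otus)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    log_lo, log_hi = np.log(config.base_rate_range[0]), np.log(config.base_rate_range[1])
    base_rates = np.exp(base_rng.uniform(log_lo, log_hi, size=config.n_otus))

    counts = np.zeros((config.n_otus, n), dtype=np.int64)
    expected = np.zeros((config.n_otus, n))
    otu_ids = [f"otu{j:04d}" for j in range(config.n_otus)]
    differential: dict[str, tuple[tuple[tuple[str, str], ...], float]] = {}
    zero_keep = 1.0 - config.zero_inflation
    for j in range(config.n_otus):
        effect = np.zeros(n)
        if j in config.planted:
            affected, lfc = config.planted[j]
            affected_set = {tuple(g) for g in affected}
            mask = np.array([g in affected_set for g in sample_group])
            effect[mask] = lfc
            differential[otu_ids[j]] = (tuple(tuple(g) for g in affected), lfc)
        mu = library * base_rates[j] * np.exp(effect)
        rng = np.random.default_rng(otu_seqs[j])
        counts[j] = _draw_counts(rng, mu, config.model, config.dispersion, config.zero_inflation)
        if config.model in ("ZIP", "ZINB"):
            expected[j] = zero_keep * mu
        else:
            expected[j] = mu

    lineages = {o: ("Bacteria",) + ("unclassified",) * 6 for o in otu_ids}
    table = AbundanceTable(otu_ids, lineages, counts, sample_ids)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "city": [g[0] for g in sample_group],
                "year": [g[1] for g in sample_group],
                "total_reads": library,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        differential=differential,
        expected_rates=pd.DataFrame(expected, index=otu_ids, columns=sample_ids),
    )
    return table, meta, truth


#: realistic June covariate ranges: temperatures degrees C, rainfall mm,
#: population in thousands, density persons per km^2
DEFAULT_COVARIATE_RANGES = {
    "min_temp": (0.0, 22.0),
    "temp_spread": (4.0, 15.0),
    "rainfall": (0.0, 300.0),
    "total_population": (300.0, 20000.0),
    "population_density": (100.0, 12000.0),
}


def simulate_city_table(
    n_cities: int = 16,
    ranges: Optional[dict] = None,
    seed: int = 0,
    city_names: Optional[Sequence[str]] = None,
) -> CityCovariates:
    """Uniformly drawn city covariates; max_temp = min_temp + positive spread."""
    ranges = {**DEFAULT_COVARIATE_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    if city_names is None:
        city_names = [f"city{i:02d}" for i in range(n_cities)]
    rows = {}
    min_t = rng.uniform(*ranges["min_temp"], size=n_cities)
    rows["min_temp"] = min_t
    rows["max_temp"] = min_t + rng.uniform(*ranges["temp_spread"], size=n_cities)
    for name in ("rainfall", "total_population", "population_density"):
        rows[name] = rng.uniform(*ranges[name], size=n_cities)
    frame = pd.DataFrame(rows, index=pd.Index(city_names, name="city"))
    return CityCovariates(frame)


def simulate_compositions_for_cities(
    covariates: CityCovariates,
    beta1,
    beta2,
    phi: float,
    n_per_city: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Dirichlet compositional triplets for every city's covariate row.

    Returns a table (city, y1, y2, y3) and the truth record (coefficients,
    phi, per-city mean triples).
    """
    cities = list(covariates.frame.index)
    X = covariates.design_matrix(cities)
    X_rep = np.repeat(X, n_per_city, axis=0)
    comps = simulate_dirichlet(X_rep, beta1, beta2, phi, seed=seed)
    frame = pd.DataFrame(comps, columns=["y1", "y2", "y3"])
    frame.insert(0, "city", np.repeat(cities, n_per_city))
    truth = {
        "beta1": np.asarray(beta1, float),
        "beta2": np.asarray(beta2, float),
        "phi": float(phi),
        "city_means": pd.DataFrame(
            predict_means(X, beta1, beta2), index=cities, columns=["mu1", "mu2", "mu3"]
        ),
    }
    return frame, truth
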