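"""Synthetic NIR spectra, reference chemistry and extraction data.

The generator emulates the statistical structure of two real-world
calibration exercises — strawberry-leaf nutrient analysis and
growing-media (compost / plant-fibre / spent-substrate) analysis —
without any physically meaningful band assignments:

* Concentrations are drawn from a range-truncated correlated normal
  model whose latent parameters are moment-matched so the *truncated*
  marginals hit the configured means and SDs wherever that is feasible.
* Each constituent absorbs through a few Gaussian bands in the
  overtone/combination region (1100-2500 nm by default); a spectrum's
  clean signal is the concentration-weighted sum of those band spectra
  (a Beer-Lambert linear mixture).
* Each replicate scan is corrupted by multiplicative scatter, an
  additive offset, a wavelength-linear tilt and white noise; the stored
  spectrum is the replicate average (two scans by default, matching
  standard duplicate-scan practice).

Everything is driven by one integer seed; identical config + seed give
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .amac import AMAC_EQUATIONS
from .containers import ReferenceTable, SpectraSet

__all__ = [
    "ComponentBand",
    "SimulationConfig",
    "SyntheticDataset",
    "nearest_psd_correlation",
    "generate_concentrations",
    "generate_spectra",
    "generate_dataset",
    "generate_amac_pairs",
    "split_calibration_validation",
    "leaf_config",
    "media_config",
]

WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 2500.0
WAVELENGTH_STEP = 0.5

#: default AmAc ranges (g/L substrate) per element, sized so the printed
#: sqrt-scale relations give mostly positive totals (Ca and Mg carry
#: negative intercepts and need higher extractable levels)
DEFAULT_AMAC_RANGES: dict[str, tuple[float, float]] = {
    "P": (0.5, 8.0),
    "K": (0.5, 8.0),
    "Ca": (40.0, 400.0),
    "Mg": (10.0, 100.0),
}


@dataclass(frozen=True)
class ComponentBand:
    """One Gaussian absorption band of a constituent."""

    center: float     # nm
    width: float      # Gaussian sigma, nm
    amplitude: float  # absorbance per unit concentration

    def __post_init__(self) -> None:
        if not (WAVELENGTH_MIN <= self.center <= WAVELENGTH_MAX):
            raise ValueError(f"band center {self.center} nm outside grid")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wavelengths - self.center) / self.width) ** 2)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset generator."""

    n_samples: int
    constituents: list[str]
    concentration_means: dict[str, float]
    concentration_sds: dict[str, float]
    concentration_ranges: dict[str, tuple[float, float]]
    correlation_matrix: np.ndarray
    seed: int
    bands_per_constituent: int = 3
    band_region: tuple[float, float] = (1100.0, 2500.0)
    band_width_range: tuple[float, float] = (20.0, 80.0)
    target_band_absorbance: float = 0.3
    background_bands: int = 4
    background_amplitude: float = 1.0
    scatter_sigma: float = 0.05
    baseline_coeffs_sigma: float = 0.02
    noise_sd: float = 1e-4
    n_replicate_scans: int = 2

    def __post_init__(self) -> None:
        self.correlation_matrix = np.asarray(self.correlation_matrix, dtype=float)
        k = len(self.constituents)
        if self.correlation_matrix.shape != (k, k):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.correlation_matrix, self.correlation_matrix.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation_matrix), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if self.n_replicate_scans < 1:
            raise ValueError("n_replicate_scans must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for c in self.constituents:
            lo, hi = self.concentration_ranges[c]
            m = self.concentration_means[c]
            if not lo <= m <= hi:
                raise ValueError(f"range for {c} does not contain its mean")
            if self.concentration_sds[c] < 0:
                raise ValueError(f"negative SD for {c}")


@dataclass
class SyntheticDataset:
    """Spectra + reference chemistry + generating component spectra."""

    spectra: SpectraSet
    reference: ReferenceTable
    true_component_spectra: np.ndarray  # (constituent, wavelength)
    background_spectrum: np.ndarray | None = None  # matrix absorbance (wavelength,)
    split_labels: pd.Series | None = None  # "calibration" / "validation"

    def __post_init__(self) -> None:
        if set(self.spectra.sample_ids) != set(self.reference.sample_ids):
            raise ValueError("spectra and reference sample ids differ")

    def subset(self, label: str) -> "SyntheticDataset":
        if self.split_labels is None:
            raise ValueError("dataset has no split labels")
        ids = self.split_labels.index[self.split_labels == label].tolist()
        if not ids:
            raise ValueError(f"no samples with label {label!r}")
        return SyntheticDataset(
            self.spectra.select(ids), self.reference.select(ids),
            self.true_component_spectra,
            self.background_spectrum,
            self.split_labels.loc[ids],
        )


def nearest_psd_correlation(R: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix
    (eigenvalue clipping followed by unit-diagonal rescaling)."""
    R = np.asarray(R, dtype=float)
    vals, vecs = np.linalg.eigh((R + R.T) / 2)
    if vals.min() >= 0:
        out = R.copy()
    else:
        vals = np.clip(vals, 1e-10, None)
        out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _match_truncated_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Latent (mu, sigma) of a normal whose [lo, hi]-truncation has
    (approximately) the requested mean and SD.

    When the range already covers mean +/- 4 SD the truncation is
    negligible and the targets are returned unchanged.  When no
    truncated normal on [lo, hi] can reach the target SD (hard ranges
    cap the SD below the half-width), the fit saturates at its bounds
    and the achievable moments are as close as the model allows.
    """
    if sd == 0:
        return mean, 0.0
    if lo <= mean - 4 * sd and hi >= mean + 4 * sd:
        return mean, sd

    def resid(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [(m - mean) / sd, (np.sqrt(v) - sd) / sd]

    sol = optimize.least_squares(
        resid, x0=[mean, np.log(sd)],
        bounds=([lo - 10 * sd, np.log(sd * 0.2)], [hi + 10 * sd, np.log(sd * 5.0)]),
    )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def generate_concentrations(config: SimulationConfig) -> ReferenceTable:
    """Draw correlated, range-truncated constituent concentrations.

    Sampling uses a Gaussian copula with the configured correlation
    matrix and per-constituent truncated-normal marginals whose latent
    parameters are moment-matched to the configured mean/SD.  Every
    value is inside its configured range by construction, marginals are
    decoupled from one another, and the rank dependence of the copula
    preserves the configured correlations up to a small monotone-
    transform attenuation.
    """
    R = config.correlation_matrix
    vals = np.linalg.eigvalsh((R + R.T) / 2)
    if vals.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not positive semi-definite (min eigenvalue {vals.min():.3g}); "
            "project it with nearest_psd_correlation first"
        )
    rng = np.random.default_rng(config.seed)
    k = len(config.constituents)
    mus = np.empty(k)
    sigmas = np.empty(k)
    los = np.empty(k)
    his = np.empty(k)
    for i, c in enumerate(config.constituents):
        lo, hi = config.concentration_ranges[c]
        mu, sigma = _match_truncated_params(
            config.concentration_means[c], config.concentration_sds[c], lo, hi
        )
        mus[i], sigmas[i], los[i], his[i] = mu, sigma, lo, hi

    if np.all(sigmas == 0):
        X = np.tile(mus, (config.n_samples, 1))
    else:
        # eigendecomposition square root: tolerant of semi-definite R
        w, V = np.linalg.eigh((R + R.T) / 2)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
        Z = rng.standard_normal((config.n_samples, k)) @ L.T
        U = stats.norm.cdf(Z)
        X = np.empty_like(U)
        for i in range(k):
            if sigmas[i] == 0:
                X[:, i] = mus[i]
                continue
            a = (los[i] - mus[i]) / sigmas[i]
            b = (his[i] - mus[i]) / sigmas[i]
            X[:, i] = stats.truncnorm.ppf(U[:, i], a, b,
                                          loc=mus[i], scale=sigmas[i])

    ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    df = pd.DataFrame(X, index=ids, columns=config.constituents)
    df.index.name = "sample_id"
    return ReferenceTable(df)


def _draw_component_bands(config: SimulationConfig, rng: np.random.Generator) -> list[list[ComponentBand]]:
    lo, hi = config.band_region
    wlo, whi = config.band_width_range
    all_bands = []
    for c in config.constituents:
        mean = config.concentration_means[c]
        scale = config.target_band_absorbance / (mean if mean > 0 else 1.0)
        bands = []
        for _ in range(config.bands_per_constituent):
            center = rng.uniform(lo, hi)
            width = rng.uniform(wlo, whi)
            amplitude = rng.uniform(0.5, 1.5) * scale / config.bands_per_constituent
            bands.append(ComponentBand(center, width, amplitude))
        all_bands.append(bands)
    return all_bands


def generate_spectra(reference: ReferenceTable, config: SimulationConfig) -> SyntheticDataset:
    """Turn a concentration table into replicate-averaged noisy spectra.

    The clean signal of a sample is a fixed matrix-background spectrum
    (broad bands emulating the dominant cellulose/water absorbance of a
    dried, ground sample) plus the linear mixture
    ``sum_c concentration_c * K_c(lambda)`` of its constituents' band
    spectra; every replicate scan then receives its own multiplicative
    scatter factor, additive offset, linear tilt and white noise before
    the replicates are averaged.  Set ``background_amplitude=0`` for a
    pure mixture (the unmixing-oracle configuration).
    """
    if len(reference.sample_ids) == 0:
        raise ValueError("reference table is empty")
    unknown = [c for c in config.constituents if c not in reference.constituents]
    if unknown:
        raise ValueError(f"reference table lacks constituent(s) {unknown}")

    wavelengths = np.arange(WAVELENGTH_MIN, WAVELENGTH_MAX + WAVELENGTH_STEP / 2,
                            WAVELENGTH_STEP)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    background = np.zeros_like(wavelengths)
    if config.background_amplitude > 0 and config.background_bands > 0:
        for _ in range(config.background_bands):
            band = ComponentBand(
                center=rng.uniform(1100.0, 2450.0),
                width=rng.uniform(100.0, 300.0),
                amplitude=rng.uniform(0.5, 1.5)
                * config.background_amplitude / config.background_bands,
            )
            background += band.profile(wavelengths)
    bands = _draw_component_bands(config, rng)
    K = np.vstack([
        np.sum([b.profile(wavelengths) for b in blist], axis=0)
        for blist in bands
    ])  # (k, p)

    C = np.column_stack([reference.values_for(c) for c in config.constituents])
    clean = background + C @ K  # (n, p)
    n, p = clean.shape
    u = (wavelengths - 1450.0) / 1050.0

    acc = np.zeros((n, p))
    for _ in range(config.n_replicate_scans):
        alpha = (np.exp(rng.normal(0.0, config.scatter_sigma, size=n))
                 if config.scatter_sigma > 0 else np.ones(n))
        if config.baseline_coeffs_sigma > 0:
            b0 = rng.normal(0.0, config.baseline_coeffs_sigma, size=n)
            b1 = rng.normal(0.0, config.baseline_coeffs_sigma, size=n)
        else:
            b0 = b1 = np.zeros(n)
        rep = alpha[:, None] * clean + b0[:, None] + np.outer(b1, u)
        if config.noise_sd > 0:
            rep = rep + rng.normal(0.0, config.noise_sd, size=(n, p))
        acc += rep
    averaged = acc / config.n_replicate_scans

    spectra = SpectraSet(list(reference.sample_ids), wavelengths, averaged)
    return SyntheticDataset(spectra, reference, K, background)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Concentrations + spectra in one call."""
    return generate_spectra(generate_concentrations(config), config)


#: default sqrt-scale noise, sized so the potassium calibration on its
#: default extractable range reproduces the published calibration R^2
#: of about 0.97 (signal SD ~0.53 on the sqrt scale at that range)
DEFAULT_AMAC_NOISE_SD = 0.1


def generate_amac_pairs(element: str, n: int,
                        noise_sd_sqrt_scale: float = DEFAULT_AMAC_NOISE_SD,
                        seed: int = 0,
                        amac_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Synthetic (extractable, total) nutrient pairs in g/L substrate.

    Pairs follow ``sqrt(total) = a * sqrt(amac) + b + eps`` with the
    element's published sqrt-scale calibration coefficients and Gaussian
    noise on the sqrt scale; negative implied sqrt-totals truncate to 0.
    """
    if element not in AMAC_EQUATIONS:
        raise ValueError(f"unknown element {element!r}; have {sorted(AMAC_EQUATIONS)}")
    if noise_sd_sqrt_scale < 0:
        raise ValueError("noise sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = AMAC_EQUATIONS[element]
    lo, hi = amac_range if amac_range is not None else DEFAULT_AMAC_RANGES[element]
    if lo <= 0 or hi <= lo:
        raise ValueError("amac range must be positive and increasing")
    rng = np.random.default_rng(seed)
    amac = rng.uniform(lo, hi, size=n)
    sqrt_total = a * np.sqrt(amac) + b
    if noise_sd_sqrt_scale > 0:
        sqrt_total = sqrt_total + rng.normal(0.0, noise_sd_sqrt_scale, size=n)
    total = np.clip(sqrt_total, 0.0, None) ** 2
    return pd.DataFrame({
        "element": element,
        "amac_g_per_L": amac,
        "total_g_per_L": total,
    })


def split_calibration_validation(dataset: SyntheticDataset,
                                 validation_fraction: float,
                                 seed: int) -> SyntheticDataset:
    """Randomly label samples calibration/validation (both non-empty)."""
    if not 0 < validation_fraction < 1:
        raise ValueError("validation fraction must be in (0, 1)")
    ids = dataset.spectra.sample_ids
    n = len(ids)
    n_val = int(round(validation_fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError(
            f"fraction {validation_fraction} would leave an empty subset (n={n})"
        )
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(n, size=n_val, replace=False).tolist())
    labels = pd.Series(
        ["validation" if i in val_idx else "calibration" for i in range(n)],
        index=ids, name="split",
    )
    return replace(dataset, split_labels=labels)


# ----------------------------------------------------------------------
# presets emulating the two study datasets
# ----------------------------------------------------------------------

def _build_correlation(constituents: list[str],
                       pinned: dict[tuple[str, str], float],
                       default: float = 0.3) -> np.ndarray:
    k = len(constituents)
    R = np.full((k, k), default)
    np.fill_diagonal(R, 1.0)
    idx = {c: i for i, c in enumerate(constituents)}
    for (a, b), r in pinned.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return nearest_psd_correlation(R)


def leaf_config(n_samples: int = 369, seed: int = 0, **overrides) -> SimulationConfig:
    """Strawberry-leaf preset: N in %/DM, the rest in mg/kg DM.

    Means/SDs follow the leaf calibration summary statistics; N, P and K
    ranges follow the published spans (0.6-3.5 %/DM N, 0.7-6.3 g P and
    2-29 g K per kg DM); Mg and Ca ranges default to mean +/- 4 SD
    floored at zero.  Pinned correlations: corr(P, K) = 0.80 and
    corr(Mg, Ca) = -0.22.
    """
    constituents = ["N", "P", "K", "Mg", "Ca"]
    means = {"N": 1.8, "P": 2890.0, "K": 16054.0, "Mg": 4203.0, "Ca": 13591.0}
    sds = {"N": 0.6, "P": 1111.0, "K": 9560.0, "Mg": 837.0, "Ca": 4626.0}
    ranges = {
        "N": (0.6, 3.5),
        "P": (700.0, 6300.0),
        "K": (2000.0, 29000.0),
        "Mg": (max(means["Mg"] - 4 * sds["Mg"], 0.0), means["Mg"] + 4 * sds["Mg"]),
        "Ca": (max(means["Ca"] - 4 * sds["Ca"], 0.0), means["Ca"] + 4 * sds["Ca"]),
    }
    R = _build_correlation(constituents, {("P", "K"): 0.80, ("Mg", "Ca"): -0.22})
    cfg = dict(
        n_samples=n_samples, constituents=constituents,
        concentration_means=means, concentration_sds=sds,
        concentration_ranges=ranges, correlation_matrix=R, seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def media_config(n_samples: int = 567, seed: int = 0, **overrides) -> SimulationConfig:
    """Growing-media preset (composts, plant fibres, spent substrates).

    Means/SDs follow the growing-media calibration summary statistics;
    ranges default to mean +/- 4 SD floored at zero.  Pinned
    correlations: corr(Mg, Ca) = 0.88, corr(Mg, K) = corr(N, K) = 0.49.
    """
    constituents = ["N", "P", "K", "Mg", "Ca", "OM", "pH", "EC", "C/N", "C/P"]
    means = {"N": 1.042, "P": 1508.0, "K": 5892.0, "Mg": 2444.0, "Ca": 15500.0,
             "OM": 61.9, "pH": 7.00, "EC": 526.0, "C/N": 43.0, "C/P": 312.0}
    sds = {"N": 0.468, "P": 903.0, "K": 4349.0, "Mg": 1359.0, "Ca": 8501.0,
           "OM": 26.4, "pH": 1.38, "EC": 509.0, "C/N": 41.7, "C/P": 265.0}
    ranges = {c: (max(means[c] - 4 * sds[c], 0.0), means[c] + 4 * sds[c])
              for c in constituents}
    ranges["OM"] = (ranges["OM"][0], 100.0)  # %/DM cannot exceed 100
    ranges["pH"] = (2.0, 12.0)
    R = _build_correlation(constituents, {
        ("Mg", "Ca"): 0.88, ("Mg", "K"): 0.49, ("N", "K"): 0.49,
    })
    cfg = dict(
        n_samples=n_samples, constituents=constituents,
        concentration_means=means, concentration_sds=sds,
        concentration_ranges=ranges, correlation_matrix=R, seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
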