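"""Bayesian estimation of dummy-atom form factors from reference curves.

For each q-bin independently, the posterior of the 20- or 21-dimensional
form-factor vector f under a uniform box prior [0, f_max]^L is

    P(f | I_q,1..N) ∝ prod_i N(I_q,i | I'_q,i(f, X_i), sigma_q,i)

where I'_q,i is the Debye intensity of training structure X_i under f and
sigma_q,i comes from the error model applied to the reference intensity of
structure i.  The posterior is explored by Metropolis-Hastings with a
truncated-uniform single-component proposal, and the point estimate for the
bin is the medoid of the retained samples (the sampled vector with the
smallest summed Euclidean distance to all others).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from ._kernels import run_chain
from .curves import ScatteringCurve
from .debye import FormFactorTable, QGrid, type_pair_kernel
from .scoring import ErrorModel
from .structure import BeadAlphabet, CoarseStructure


class InferenceError(ValueError):
    """Raised for invalid sampler configuration or training input."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    f_max bounds the box prior (well beyond published dummy-atom form
    factors); m is the half-width of the truncated-uniform component
    proposal.  Thinning keeps the exact O(T^2) medoid computation cheap.
    """

    f_max: float = 40.0
    m: float = 1.5
    iterations: int = 200_000
    burn_in: int = 50_000
    thinning: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.m <= self.f_max):
            raise InferenceError("need 0 < m <= f_max")
        if self.iterations <= self.burn_in:
            raise InferenceError("iterations must exceed burn-in")
        if self.thinning < 1:
            raise InferenceError("thinning stride must be >= 1")


@dataclass
class SampleSet:
    """Posterior draws of the form-factor vector for one q-bin."""

    bin_index: int
    samples: np.ndarray          # (T, L)
    acceptance_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] < 1:
            raise InferenceError("need at least one sample")


@dataclass
class TrainingSet:
    """Paired coarse structures and reference curves on a common grid."""

    pairs: list[tuple[CoarseStructure, ScatteringCurve]]
    grid: QGrid = field(default_factory=QGrid)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise InferenceError("training set is empty")
        grans = {s.granularity for s, _ in self.pairs}
        if len(grans) != 1:
            raise InferenceError("mixed granularities in training set")
        self.alphabet = BeadAlphabet.for_granularity(grans.pop())
        for _, curve in self.pairs:
            if len(curve) != self.grid.n_bins or not np.allclose(
                    curve.q, self.grid.q, atol=1e-9, rtol=0):
                raise InferenceError("training curve grid does not match q-grid")
        self._kernels: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def kernels(self) -> np.ndarray:
        """(N, L, L, Q) precomputed geometry kernels G_i."""
        if self._kernels is None:
            self._kernels = np.stack([
                type_pair_kernel(s, self.alphabet, self.grid)
                for s, _ in self.pairs
            ])
        return self._kernels

    @property
    def reference_intensities(self) -> np.ndarray:
        """(N, Q) reference intensities."""
        return np.stack([c.intensity for _, c in self.pairs])

    def sigma_matrix(self, model: ErrorModel, scale: float = 1.0) -> np.ndarray:
        """(N, Q) per-structure likelihood standard deviations.

        ``scale`` multiplies the error-model sigma; the per-curve floor of
        1e-12 * max(I) always applies, so ``scale=0`` yields the
        vanishing-noise limit in which the posterior collapses onto exact
        fits of the reference intensities.
        """
        if scale < 0:
            raise InferenceError("sigma scale must be nonnegative")
        rows = []
        for _, c in self.pairs:
            s = model.sigma(c.q, c.intensity)
            peak = float(c.intensity.max())
            floor = 1e-12 * peak if peak > 0 else 1e-30
            rows.append(np.maximum(scale * s, floor))
        return np.stack(rows)


def bin_log_posterior(
    fvec: np.ndarray,
    bin_index: int,
    train: TrainingSet,
    model: ErrorModel | None = None,
    f_max: float = 40.0,
) -> float:
    """Unnormalized log posterior of a form-factor vector at one bin.

    Returns -inf outside the box prior [0, f_max]^L.
    """
    if not 0 <= bin_index < train.grid.n_bins:
        raise InferenceError(f"bin index {bin_index} out of range")
    fvec = np.asarray(fvec, dtype=float)
    if fvec.shape != (len(train.alphabet.labels),):
        raise InferenceError("form-factor vector length does not match alphabet")
    if np.any(fvec < 0) or np.any(fvec > f_max):
        return -np.inf
    model = model or ErrorModel()
    G = train.kernels[:, :, :, bin_index]
    I_ref = train.reference_intensities[:, bin_index]
    sigma = train.sigma_matrix(model)[:, bin_index]
    I_calc = np.einsum("t,ntu,u->n", fvec, G, fvec)
    r = (I_ref - I_calc) / sigma
    return float(np.sum(-0.5 * r * r - np.log(sigma)
                        - 0.5 * np.log(2 * np.pi)))


def propose(fvec: np.ndarray, rng: np.random.Generator, config: MCMCConfig):
    """Truncated-uniform single-component proposal.

    Re-samples one randomly chosen component f uniformly from
    [max(0, f-m), min(f_max, f+m)] and returns
    (new vector, log selection probability forward, log reverse), where the
    selection probability is the reciprocal window width at the current and
    proposed values respectively.
    """
    fvec = np.asarray(fvec, dtype=float)
    c = int(rng.integers(0, fvec.size))
    lo = max(0.0, fvec[c] - config.m)
    hi = min(config.f_max, fvec[c] + config.m)
    fp = rng.uniform(lo, hi)
    lo2 = max(0.0, fp - config.m)
    hi2 = min(config.f_max, fp + config.m)
    out = fvec.copy()
    out[c] = fp
    return out, -np.log(hi - lo), -np.log(hi2 - lo2)


def mh_sample_bin(
    bin_index: int,
    train: TrainingSet,
    model: ErrorModel | None = None,
    config: MCMCConfig | None = None,
    sigma_scale: float = 1.0,
    anneal: bool = False,
) -> SampleSet:
    """Metropolis-Hastings posterior sampling for one q-bin.

    The chain starts from a uniform draw in the box, runs for the configured
    number of iterations and records post-burn-in thinned states.
    Deterministic given the config seed.  ``sigma_scale`` rescales the
    likelihood standard deviations (see ``TrainingSet.sigma_matrix``); the
    default 1 is the error model's assumed experimental error.  With
    ``anneal`` the burn-in starts at the nominal (scale 1) standard
    deviations and tightens geometrically to the final ones, which lets the
    single-component chain settle into very tight posteriors; sampling
    after burn-in is always plain Metropolis-Hastings.
    """
    model = model or ErrorModel()
    config = config or MCMCConfig()
    if not 0 <= bin_index < train.grid.n_bins:
        raise InferenceError(f"bin index {bin_index} out of range")
    G = np.ascontiguousarray(train.kernels[:, :, :, bin_index])
    I_ref = train.reference_intensities[:, bin_index]
    sigma = train.sigma_matrix(model, sigma_scale)[:, bin_index]
    anneal_ratio = 1.0
    if anneal:
        nominal = train.sigma_matrix(model, 1.0)[:, bin_index]
        anneal_ratio = max(1.0, float(np.max(nominal / sigma)))
    samples, accepted = run_chain(
        G, I_ref, sigma, config.f_max, config.m,
        config.iterations, config.burn_in, config.thinning,
        int(config.seed) % 2**31, anneal_ratio,
    )
    rate = accepted / config.iterations
    if rate < 0.01:
        warnings.warn(
            f"bin {bin_index}: acceptance rate {rate:.2%} below 1%",
            stacklevel=2)
    return SampleSet(bin_index, samples, rate)


def medoid(samples: SampleSet | np.ndarray) -> np.ndarray:
    """Sample minimizing the summed Euclidean distance to all other samples.

    Ties break toward the earliest sample.
    """
    vecs = samples.samples if isinstance(samples, SampleSet) else np.asarray(samples)
    vecs = np.atleast_2d(np.asarray(vecs, dtype=float))
    if vecs.shape[0] == 0:
        raise InferenceError("empty sample set has no medoid")
    T = vecs.shape[0]
    total = np.zeros(T)
    chunk = max(1, int(2e7) // max(T, 1))
    for start in range(0, T, chunk):
        total[start:start + chunk] = cdist(vecs[start:start + chunk], vecs).sum(axis=1)
    return vecs[int(np.argmin(total))].copy()


def estimate_table(
    train: TrainingSet,
    model: ErrorModel | None = None,
    config: MCMCConfig | None = None,
    sigma_scale: float = 1.0,
    anneal: bool = False,
    restarts: int = 1,
):
    """Estimate the full form-factor table from a training set.

    Each q-bin is sampled independently with its own derived seed
    (seed + bin index), so results do not depend on execution order.
    With ``restarts > 1``, several independently seeded chains run per bin
    and the one whose medoid attains the highest posterior is kept — a
    multi-start guard for the near-degenerate regimes (tiny sigma_scale)
    where a single chain can freeze outside the global basin.
    Returns ``(table, sample_sets, diagnostics)`` where diagnostics holds
    per-bin acceptance rates and posterior-sample standard deviations.
    """
    model = model or ErrorModel()
    config = config or MCMCConfig()
    nbins = train.grid.n_bins
    L = len(train.alphabet.labels)
    values = np.empty((L, nbins))
    sample_sets: list[SampleSet] = []
    acc = []
    spread = np.empty((L, nbins))
    sigma_final = train.sigma_matrix(model, sigma_scale)
    I_ref = train.reference_intensities
    for b in range(nbins):
        best = None
        best_fit = -np.inf
        best_med = None
        for r in range(max(1, restarts)):
            ss = mh_sample_bin(
                b, train, model,
                replace(config, seed=(config.seed + b + r * 7919) % 2**31),
                sigma_scale=sigma_scale, anneal=anneal)
            med = medoid(ss)
            calc = np.einsum("t,ntu,u->n", med, train.kernels[:, :, :, b], med)
            fit = -0.5 * float(np.sum(
                ((I_ref[:, b] - calc) / sigma_final[:, b]) ** 2))
            if fit > best_fit:
                best, best_fit, best_med = ss, fit, med
        values[:, b] = best_med
        spread[:, b] = best.samples.std(axis=0)
        acc.append(best.acceptance_rate)
        sample_sets.append(best)
    table = FormFactorTable(train.alphabet, train.grid, values)
    diagnostics = {
        "acceptance_rates": acc,
        "sample_sd": spread,
        "n_samples_per_bin": int(sample_sets[0].samples.shape[0]),
    }
    return table, sample_sets, diagnostics
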