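"""Pre-calibration: rejection sampling of yield-model parameter uncertainty.

Rather than a likelihood, pre-calibration screens parameter vectors by a
plausibility test: a candidate 13-coefficient vector of the *full* yield
polynomial is accepted when its regional annual hindcast stays inside a
symmetric band around the best-estimate hindcast, where the band's
half-width is the smallest value covering 95% of the observed regional
annual yield anomalies.

Candidates are drawn by Latin hypercube sampling over independent uniform
ranges per coefficient: best estimate +/- 10 standard errors, widened to
+/- 50 standard errors for the EDD terms (whose full-model and selected-
model estimates differ most). The whole pipeline streams in chunks, so
the proposal count is limited by patience, not memory (apart from one
stratum-permutation per dimension).

Because the regional hindcast is linear in the coefficients (the
area-weighted yearly means of the polynomial regressors form a fixed
matrix ``R``), screening a chunk of candidates is a single matrix
product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimates import COEF_NAMES

#: Coefficients whose sampling range uses the widened multiplier.
EDD_TERMS = ("edd", "edd2")

_JITTER_BLOCK = 1 << 16


@dataclass(frozen=True)
class SamplingRanges:
    """Independent uniform sampling box per coefficient (canonical order)."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        if not np.all(self.lo < self.hi):
            raise ValueError("every range must have lo < hi")

    @property
    def width(self) -> np.ndarray:
        return self.hi - self.lo

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lo": self.lo, "hi": self.hi}, index=list(COEF_NAMES))


@dataclass
class PlausibleBand:
    """Symmetric plausibility envelope around the best-estimate hindcast."""

    half_width: float
    reference: pd.Series          # year -> best-estimate hindcast anomaly
    coverage: float
    degenerate: bool = False


@dataclass
class AcceptedEnsemble:
    """Accepted coefficient vectors plus acceptance bookkeeping."""

    samples: np.ndarray           # (n_accepted, 13)
    n_proposed: int
    n_accepted: int
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(COEF_NAMES))


def build_ranges(
    best: np.ndarray,
    se: np.ndarray,
    k_default: float = 10.0,
    k_edd: float = 50.0,
    strict_table: dict[str, tuple[float, float]] | None = None,
) -> SamplingRanges:
    """Sampling box ``best +/- k * se`` with ``k`` widened for EDD terms.

    ``strict_table`` overrides computed ranges with externally printed
    bounds (keyed by coefficient name) — an escape hatch for reproducing a
    published table verbatim, including any misprint.
    """
    best = np.asarray(best, dtype=float)
    se = np.asarray(se, dtype=float)
    if best.shape != (len(COEF_NAMES),) or se.shape != (len(COEF_NAMES),):
        raise ValueError(f"best and se must be {len(COEF_NAMES)}-vectors")
    if np.any(se <= 0):
        bad = [n for n, s in zip(COEF_NAMES, se) if s <= 0]
        raise ValueError(f"standard errors must be positive; offending: {bad}")
    k = np.full(len(COEF_NAMES), float(k_default))
    for t in EDD_TERMS:
        k[COEF_NAMES.index(t)] = float(k_edd)
    lo, hi = best - k * se, best + k * se
    if strict_table is not None:
        for name, (a, b) in strict_table.items():
            i = COEF_NAMES.index(name)
            lo[i], hi[i] = a, b
    return SamplingRanges(lo=lo, hi=hi)


def _jitter(seed: int, dim: int, start: int, count: int) -> np.ndarray:
    """Uniform(0,1) jitter for absolute sample indices [start, start+count).

    Generated in fixed-size blocks keyed by (seed, dim, block), so the
    stream is independent of how callers chunk it.
    """
    out = np.empty(count)
    pos = 0
    b0, b1 = start // _JITTER_BLOCK, (start + count - 1) // _JITTER_BLOCK
    for b in range(b0, b1 + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7001, dim, b]))
        block = rng.random(_JITTER_BLOCK)
        lo = max(start, b * _JITTER_BLOCK)
        hi = min(start + count, (b + 1) * _JITTER_BLOCK)
        out[pos:pos + hi - lo] = block[lo - b * _JITTER_BLOCK:hi - b * _JITTER_BLOCK]
        pos += hi - lo
    return out


class LatinHypercubeStream:
    """Chunked Latin hypercube design over a sampling box.

    Each dimension's range is divided into ``n`` equal strata; across the
    whole stream each stratum is hit exactly once (an independent random
    stratum permutation per dimension, uniform jitter within strata). The
    stream is deterministic under a fixed seed and invariant to the chunk
    size used to consume it.
    """

    def __init__(self, ranges: SamplingRanges, n: int, seed: int):
        if n < 1:
            raise ValueError("n must be >= 1")
        self.ranges = ranges
        self.n = int(n)
        self.seed = int(seed)
        dtype = np.int32 if n < 2**31 else np.int64
        self._perms = [
            np.random.default_rng(np.random.SeedSequence([seed, 6001, d]))
            .permutation(self.n).astype(dtype)
            for d in range(len(COEF_NAMES))
        ]

    def chunk(self, start: int, count: int) -> np.ndarray:
        """(count, 13) coefficient matrix for sample indices [start, start+count)."""
        count = min(count, self.n - start)
        out = np.empty((count, len(COEF_NAMES)))
        lo, w = self.ranges.lo, self.ranges.width
        for d in range(len(COEF_NAMES)):
            strata = self._perms[d][start:start + count].astype(float)
            u = _jitter(self.seed, d, start, count)
            out[:, d] = lo[d] + w[d] * (strata + u) / self.n
        return out

    def __iter__(self):
        return self.iter_chunks(min(self.n, 100_000))

    def iter_chunks(self, chunk: int):
        start = 0
        while start < self.n:
            yield start, self.chunk(start, chunk)
            start += chunk


def lhs_sample(ranges: SamplingRanges, n: int, seed: int, chunk: int | None = None):
    """Iterate (start_index, matrix) chunks of an n-point Latin hypercube."""
    stream = LatinHypercubeStream(ranges, n, seed)
    return stream.iter_chunks(chunk or min(n, 100_000))


def lhs_matrix(ranges: SamplingRanges, n: int, seed: int) -> np.ndarray:
    """Materialize a full n-point Latin hypercube (small n convenience)."""
    return LatinHypercubeStream(ranges, n, seed).chunk(0, n)


def fit_band(
    reference: pd.Series,
    observations: pd.Series,
    coverage: float = 0.95,
) -> PlausibleBand:
    """Minimal symmetric band around the reference hindcast.

    The half-width is the ``ceil(coverage * n)``-th smallest absolute
    residual |observation - reference| — the exact minimizer of the width
    subject to covering the target fraction of years.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    ref = pd.Series(reference, dtype=float)
    obs = pd.Series(observations, dtype=float)
    if set(ref.index) != set(obs.index):
        raise KeyError("reference and observations must cover the same years")
    if len(ref) < 2:
        raise ValueError("need at least 2 years to fit a band")
    resid = np.sort(np.abs(obs.sort_index().to_numpy() - ref.sort_index().to_numpy()))
    m = int(np.ceil(coverage * len(resid)))
    half_width = float(resid[m - 1])
    return PlausibleBand(
        half_width=half_width, reference=ref.sort_index(), coverage=coverage,
        degenerate=half_width == 0.0,
    )


def hindcast_matrix(regional_terms: pd.DataFrame) -> np.ndarray:
    """Alias making intent explicit: rows are years, columns coefficients."""
    return regional_terms[list(COEF_NAMES)].to_numpy()


def accept(
    candidates: np.ndarray,
    regional_terms: pd.DataFrame,
    band: PlausibleBand,
    center: float = 0.0,
    coverage_accept: float | None = None,
) -> np.ndarray:
    """Vectorized acceptance test for candidate coefficient vectors.

    A candidate is accepted when its regional annual hindcast anomaly
    (``R @ beta - center``) lies within ``reference +/- half_width`` for
    *all* historical years — the strict reading of "hindcast falls within
    the plausible range". ``coverage_accept`` relaxes this to a fraction
    of years (e.g. 0.95).

    Returns a boolean array; scalar input gives a length-1 array.
    """
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    R = hindcast_matrix(regional_terms)
    years = regional_terms.index
    ref = band.reference.loc[years].to_numpy()
    H = C @ R.T - center
    inside = np.abs(H - ref) <= band.half_width + 1e-12 * max(1.0, band.half_width)
    if coverage_accept is None:
        return inside.all(axis=1)
    need = int(np.ceil(coverage_accept * inside.shape[1]))
    return inside.sum(axis=1) >= need


def run_precalibration(
    ranges: SamplingRanges,
    regional_terms: pd.DataFrame,
    band: PlausibleBand,
    n: int,
    seed: int,
    chunk: int = 100_000,
    center: float = 0.0,
    coverage_accept: float | None = None,
) -> AcceptedEnsemble:
    """Stream an n-point Latin hypercube through the acceptance test.

    Evaluation memory is bounded by the chunk size; the accepted set is
    independent of the chunking.
    """
    accepted = []
    n_acc = 0
    for start, C in lhs_sample(ranges, n, seed, chunk):
        keep = accept(C, regional_terms, band, center=center,
                      coverage_accept=coverage_accept)
        if keep.any():
            accepted.append(C[keep])
            n_acc += int(keep.sum())
    samples = np.concatenate(accepted) if accepted else np.empty((0, len(COEF_NAMES)))
    if n_acc == 0:
        warnings.warn(
            f"pre-calibration accepted 0 of {n} samples "
            f"(band half-width {band.half_width:.3g}); widen the proposal count, "
            "check the band, or inspect the hindcast alignment",
            RuntimeWarning, stacklevel=2,
        )
    return AcceptedEnsemble(samples=samples, n_proposed=int(n), n_accepted=n_acc, seed=seed)


def run_precalibration_gaussian(
    ranges: SamplingRanges,
    regional_terms: pd.DataFrame,
    band: PlausibleBand,
    best: np.ndarray,
    cov: np.ndarray,
    n: int,
    seed: int,
    chunk: int = 100_000,
    center: float = 0.0,
    inflation: float = 3.0,
    coverage_accept: float | None = None,
) -> AcceptedEnsemble:
    """The same plausibility screen with fit-informed Gaussian proposals.

    Blind Latin hypercube proposals over the +/-10/50-SE box have a
    vanishing chance of landing inside the plausible band at desk-scale
    proposal counts (the box-to-band volume ratio is astronomical; the
    published analysis burned 1e10 draws for ~2e4 acceptances). This
    variant applies the *identical* acceptance test to proposals drawn
    from the regression's sampling distribution N(best, inflation^2 * cov),
    truncated to the sampling box, so usable accepted ensembles exist at
    small proposal counts. The inflation factor keeps the proposal wide
    relative to the regression uncertainty, preserving the screen's role
    of discovering acceptable parameters away from the best estimate.
    """
    best = np.asarray(best, dtype=float)
    cov = np.asarray(cov, dtype=float)
    # factor the correlation matrix: coefficient scales differ by ~10 orders
    # of magnitude, so a direct Cholesky of cov loses the small coordinates
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        raise ValueError("cov must have positive diagonal for every coefficient")
    corr = cov / np.outer(sd, sd)
    L = np.linalg.cholesky(corr + 1e-10 * np.eye(len(best)))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    accepted = []
    n_acc = 0
    done = 0
    while done < n:
        m = min(chunk, n - done)
        C = best + inflation * (rng.standard_normal((m, len(best))) @ L.T) * sd
        keep = ranges.contains(C)
        keep &= accept(C, regional_terms, band, center=center,
                       coverage_accept=coverage_accept)
        if keep.any():
            accepted.append(C[keep])
            n_acc += int(keep.sum())
        done += m
    samples = np.concatenate(accepted) if accepted else np.empty((0, len(COEF_NAMES)))
    if n_acc == 0:
        warnings.warn(
            f"gaussian-proposal screen accepted 0 of {n} samples "
            f"(band half-width {band.half_width:.3g})",
            RuntimeWarning, stacklevel=2,
        )
    return AcceptedEnsemble(samples=samples, n_proposed=int(n), n_accepted=n_acc, seed=seed)


def convergence_diagnostic(
    ensemble: AcceptedEnsemble | np.ndarray,
    projector,
    step: int = 100,
) -> pd.DataFrame:
    """Running mean and SD of a projection over accepted-sample prefixes.

    ``projector`` maps an (m, 13) coefficient matrix to projections — one
    scalar per sample, or a row per sample when each parameter sample is
    crossed with several forcings (rows are pooled). Returns a table with
    one row per prefix size ``step, 2*step, ..., n`` — the stabilization
    check for "how many accepted samples are enough".
    """
    samples = ensemble.samples if isinstance(ensemble, AcceptedEnsemble) else np.asarray(ensemble)
    if len(samples) == 0:
        raise ValueError("ensemble is empty")
    proj = np.asarray(projector(samples), dtype=float)
    if proj.ndim == 1:
        proj = proj[:, None]
    n = proj.shape[0]
    sizes = list(range(step, n, step)) + [n]
    rows = [
        {"m": m, "mean": float(proj[:m].mean()), "sd": float(proj[:m].std(ddof=0))}
        for m in sizes
    ]
    return pd.DataFrame(rows)
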