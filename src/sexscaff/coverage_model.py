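"""Per-sex depth emission mixture and HMM segmentation of depth tracks.

The emission law follows the coverage-classification idea used for
linked-read contig triage: window depths are modelled as a mixture of two
Gaussians anchored at 50% and 100% of the expected full (base) depth, plus a
zeta-distributed (discrete power-law) component absorbing the outlier
windows that sit near 0% or far above 100%. Segmentation uses a 4-state HMM
(ZERO, HALF, FULL, EXCESS) with a symmetric self-transition (persistence)
probability, decoded by Viterbi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import zipf

from .core import STATE_LEVEL, CovState, DepthTrack

__all__ = [
    "EmissionModel",
    "StateSegmentation",
    "fit_emissions",
    "segment_track",
    "classify_windows",
]

#: depths at or above this multiple of base depth decode as EXCESS, below as ZERO
EXCESS_FACTOR = 1.5
#: Gaussian means are constrained to +/- this fraction of their anchors
MEAN_SLACK = 0.20
_MIN_SIGMA = 0.5
_MIN_WEIGHT = 1e-6


def _zeta_logpmf(depths: np.ndarray, s: float) -> np.ndarray:
    """Log-pmf of the outlier component: depth mapped to positive integers."""
    k = np.floor(depths).astype(np.int64) + 1
    return zipf.logpmf(k, s)


def _norm_logpdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -0.5 * math.log(2 * math.pi) - math.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


@dataclass
class EmissionModel:
    """Fitted 3-component emission mixture for one sex's depth windows."""

    mu_half: float
    mu_full: float
    sigma_half: float
    sigma_full: float
    zeta_exponent: float
    zero_mass: float
    weights: np.ndarray  # (half, full, outlier), sums to 1
    base_depth: float
    log_likelihood: float = math.nan
    n_iter: int = 0
    degenerate: bool = False
    ll_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.degenerate:
            if abs(self.weights.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if not self.mu_half < self.mu_full:
                raise ValueError("mu_half must be < mu_full")
            if self.zeta_exponent <= 1:
                raise ValueError("zeta exponent must be > 1")

    def state_log_emissions(self, depths: np.ndarray) -> np.ndarray:
        """(4, T) per-state log emission densities for the HMM.

        ZERO and EXCESS share the zeta-tailed outlier law, split at
        ``EXCESS_FACTOR * base_depth``; HALF and FULL use the Gaussians.
        """
        d = np.asarray(depths, dtype=float)
        out = np.full((4, d.size), -np.inf)
        lz = _zeta_logpmf(d, self.zeta_exponent)
        hi = d >= EXCESS_FACTOR * self.base_depth
        out[CovState.ZERO, ~hi] = lz[~hi]
        out[CovState.EXCESS, hi] = lz[hi]
        out[CovState.HALF] = _norm_logpdf(d, self.mu_half, self.sigma_half)
        out[CovState.FULL] = _norm_logpdf(d, self.mu_full, self.sigma_full)
        return out

    # ------------------------------------------------------------- flat text

    def save(self, path) -> None:
        import yaml

        doc = {
            "mu_half": float(self.mu_half),
            "mu_full": float(self.mu_full),
            "sigma_half": float(self.sigma_half),
            "sigma_full": float(self.sigma_full),
            "zeta_exponent": float(self.zeta_exponent),
            "zero_mass": float(self.zero_mass),
            "weight_half": float(self.weights[0]),
            "weight_full": float(self.weights[1]),
            "weight_outlier": float(self.weights[2]),
            "base_depth": float(self.base_depth),
            "log_likelihood": float(self.log_likelihood),
            "degenerate": bool(self.degenerate),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "EmissionModel":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            mu_half=doc["mu_half"],
            mu_full=doc["mu_full"],
            sigma_half=doc["sigma_half"],
            sigma_full=doc["sigma_full"],
            zeta_exponent=doc["zeta_exponent"],
            zero_mass=doc["zero_mass"],
            weights=np.array([doc["weight_half"], doc["weight_full"], doc["weight_outlier"]]),
            base_depth=doc["base_depth"],
            log_likelihood=doc.get("log_likelihood", math.nan),
            degenerate=doc.get("degenerate", False),
        )


def fit_emissions(
    tracks: list[DepthTrack],
    base_depth: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> EmissionModel:
    """EM fit of the Gaussian+Gaussian+zeta mixture to pooled window depths.

    Gaussian means start at 0.5x and 1.0x ``base_depth`` and stay within
    +/-20% of those anchors; the zeta exponent is re-estimated each M-step
    by maximum likelihood on the responsibility-weighted windows. Iteration
    stops when the log-likelihood gain drops below ``tol``.
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be > 0")
    d = np.concatenate([t.depths for t in tracks]) if tracks else np.array([])
    if d.size < 100:
        raise ValueError("need at least 100 windows to fit the emission mixture")
    if np.ptp(d) == 0:
        # all windows identical: nothing to separate
        return EmissionModel(
            mu_half=float(d[0]) - 1.0,
            mu_full=float(d[0]),
            sigma_half=_MIN_SIGMA,
            sigma_full=_MIN_SIGMA,
            zeta_exponent=2.0,
            zero_mass=0.0,
            weights=np.array([0.0, 1.0, 0.0]),
            base_depth=base_depth,
            degenerate=True,
        )

    mu = np.array([0.5 * base_depth, 1.0 * base_depth])
    lo = mu * (1 - MEAN_SLACK)
    hi = mu * (1 + MEAN_SLACK)
    sigma = np.array([0.07 * base_depth, 0.07 * base_depth])
    s = 2.0
    w = np.array([0.45, 0.45, 0.10])
    ll_hist: list[float] = []
    ll_prev = -np.inf
    n_iter = 0
    resp = None
    for n_iter in range(1, max_iter + 1):
        logp = np.vstack(
            [
                np.log(w[0] + _MIN_WEIGHT) + _norm_logpdf(d, mu[0], sigma[0]),
                np.log(w[1] + _MIN_WEIGHT) + _norm_logpdf(d, mu[1], sigma[1]),
                np.log(w[2] + _MIN_WEIGHT) + _zeta_logpmf(d, s),
            ]
        )
        m = logp.max(axis=0)
        ll = float((m + np.log(np.exp(logp - m).sum(axis=0))).sum())
        ll_hist.append(ll)
        resp = np.exp(logp - m - np.log(np.exp(logp - m).sum(axis=0)))
        if ll - ll_prev < tol and n_iter > 1:
            break
        ll_prev = ll
        # M-step
        nk = resp.sum(axis=1)
        w = nk / nk.sum()
        for c in range(2):
            if nk[c] > _MIN_WEIGHT:
                mu[c] = float(np.clip((resp[c] * d).sum() / nk[c], lo[c], hi[c]))
                var = (resp[c] * (d - mu[c]) ** 2).sum() / nk[c]
                sigma[c] = max(math.sqrt(var), _MIN_SIGMA)
        if nk[2] > _MIN_WEIGHT:
            k = np.floor(d).astype(np.int64) + 1
            r2 = resp[2]

            def _nll(sv: float) -> float:
                return -float((r2 * zipf.logpmf(k, sv)).sum())

            opt = minimize_scalar(_nll, bounds=(1.05, 8.0), method="bounded")
            s = float(opt.x)

    outlier_near_zero = float(
        resp[2, d < EXCESS_FACTOR * base_depth].sum() / max(resp[2].sum(), _MIN_WEIGHT)
    )
    return EmissionModel(
        mu_half=float(mu[0]),
        mu_full=float(mu[1]),
        sigma_half=float(sigma[0]),
        sigma_full=float(sigma[1]),
        zeta_exponent=s,
        zero_mass=outlier_near_zero,
        weights=w,
        base_depth=base_depth,
        log_likelihood=ll_hist[-1],
        n_iter=n_iter,
        ll_history=ll_hist,
    )


@dataclass
class StateSegmentation:
    """Viterbi state path over one contig's windows, with merged segments."""

    contig_id: str
    states: np.ndarray  # CovState codes per window
    log_likelihood: float
    segments: list[tuple[int, int, CovState]]  # inclusive 0-based window spans

    @property
    def n_windows(self) -> int:
        return int(self.states.size)


def _segments_from_states(states: np.ndarray) -> list[tuple[int, int, CovState]]:
    segs: list[tuple[int, int, CovState]] = []
    start = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[start]:
            segs.append((start, i - 1, CovState(int(states[start]))))
            start = i
    return segs


def segment_track(
    track: DepthTrack, model: EmissionModel, persistence: float = 0.99
) -> StateSegmentation:
    """Viterbi decoding of the 4-state coverage HMM on one depth track.

    Transitions: self-transition probability ``persistence``, remaining mass
    split uniformly over the other three states; uniform initial
    distribution.
    """
    if track.n_windows == 0:
        raise ValueError("cannot segment an empty track")
    if not 0.5 <= persistence < 1.0:
        raise ValueError("persistence must be in [0.5, 1)")
    loge = model.state_log_emissions(track.depths)  # (4, T)
    T = loge.shape[1]
    log_stay = math.log(persistence)
    log_move = math.log((1 - persistence) / 3.0)
    trans = np.full((4, 4), log_move)
    np.fill_diagonal(trans, log_stay)

    delta = np.log(0.25) + loge[:, 0]
    back = np.zeros((T, 4), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(4)] + loge[:, t]
    states = np.empty(T, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    ll = float(delta[states[-1]])
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return StateSegmentation(
        contig_id=track.contig_id,
        states=states,
        log_likelihood=ll,
        segments=_segments_from_states(states),
    )


def classify_windows(seg: StateSegmentation) -> list[str]:
    """Map HMM states to the percent-coverage vocabulary (0%/50%/100%/>100%)."""
    return [STATE_LEVEL[CovState(int(s))] for s in seg.states]


def write_segmentation_bed(seg: StateSegmentation, window_size: int, path, contig_length: int | None = None) -> None:
    """Segments as BED (0-based half-open) with the state in the name column."""
    with open(path, "w") as fh:
        for start_w, end_w, state in seg.segments:
            end = (end_w + 1) * window_size
            if contig_length is not None:
                end = min(end, contig_length)
            fh.write(f"{seg.contig_id}\t{start_w * window_size}\t{end}\t{state.name}\n")
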