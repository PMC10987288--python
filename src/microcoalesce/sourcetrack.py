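"""Expectation–maximization microbial source tracking and habitat classification.

Implements the fast EM source-tracking model: a sink community (a fish gut)
is a multinomial draw from a convex mixture of source community distributions
(water and sediment samples) plus an optional "unknown" source that absorbs
sink reads unexplainable by any supplied source. The estimated mixing
proportions quantify the extent of community coalescence between the gut and
each habitat; summing them by source class (water vs sediment) yields the
record used to classify each fish's vertical habitat preference: pelagic when
the gut coalesces more with water, benthic when more with sediment.

Model. Let x_i be sink counts, s_ji source-j counts, gamma_j the source
distributions and alpha the mixing proportions. EM maximizes the joint
log-likelihood

    L = sum_j sum_i s_ji log gamma_ji + sum_i x_i log( sum_j alpha_j gamma_ji )

E-step: responsibilities r_ij = alpha_j gamma_ji / sum_l alpha_l gamma_li.
M-step: alpha_j proportional to sum_i x_i r_ij; gamma_j re-estimated from
source counts plus the sink counts assigned to j; the unknown distribution
from assigned sink counts only (it has no observed source counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class SourceTrackError(ValueError):
    """Raised for invalid source-tracking inputs."""


UNKNOWN = "unknown"

#: A sink whose unknown proportion exceeds this is flagged low-confidence.
LOW_CONFIDENCE_UNKNOWN = 0.5

#: Pseudocount added to source count vectors so no source taxon has
#: exactly zero probability (EM cannot move mass onto a hard zero).
SOURCE_PSEUDOCOUNT = 1e-6


@dataclass
class MixtureEstimate:
    """Estimated mixing proportions of one sink over named sources."""

    sink_id: str
    source_names: list[str]  # includes "unknown" last when enabled
    proportions: np.ndarray
    log_likelihood_trace: list[float]
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < -1e-12):
            raise SourceTrackError("negative mixing proportion")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise SourceTrackError("mixing proportions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.source_names, map(float, self.proportions)))


@dataclass
class CoalescenceRecord:
    """Class-summed coalescence extents and the derived habitat label."""

    sink_id: str
    water_total: float
    sediment_total: float
    unknown: float
    habitat_label: str = field(init=False)
    low_confidence: bool = field(init=False)

    def __post_init__(self) -> None:
        total = self.water_total + self.sediment_total + self.unknown
        if abs(total - 1.0) > 1e-9:
            raise SourceTrackError("coalescence totals must sum to 1")
        self.low_confidence = self.unknown > LOW_CONFIDENCE_UNKNOWN
        if self.water_total > self.sediment_total:
            self.habitat_label = "pelagic"
        elif self.sediment_total > self.water_total:
            self.habitat_label = "benthic"
        else:
            self.habitat_label = "unresolved"


def _joint_loglik(
    x: np.ndarray, padded_sources: np.ndarray, gammas: np.ndarray, alphas: np.ndarray
) -> float:
    # EM's actual objective: sink multinomial term plus the (pseudocount-
    # augmented) source multinomial terms. Using the augmented counts keeps
    # the trace exactly monotone under the M-step below.
    mix = alphas @ gammas
    sink_mask = x > 0
    ll = float((x[sink_mask] * np.log(mix[sink_mask])).sum())
    k_obs = padded_sources.shape[0]
    g_obs = np.maximum(gammas[:k_obs], 1e-300)
    ll += float((padded_sources * np.log(g_obs)).sum())
    return ll


def em_source_tracking(
    sink: np.ndarray,
    sources: Mapping[str, np.ndarray],
    sink_id: str = "sink",
    include_unknown: bool = True,
    tol: float = 1e-8,
    max_iter: int = 5000,
    n_restarts: int = 3,
    seed: int = 0,
) -> MixtureEstimate:
    """Estimate the mixing proportions of ``sink`` over named ``sources``.

    Parameters
    ----------
    sink : count vector over the shared taxon universe.
    sources : mapping of source name -> count vector (same universe).
    include_unknown : add a residual source, initialized on the positive part
        of the sink's empirical distribution minus the mean source profile
        (uniform over sink-present taxa as fallback) and re-estimated from
        assigned sink counts only. Initializing the unknown on the residual
        rather than uniformly keeps it from competing with well-fitting
        sources for source-explainable reads: the all-unknown saturated model
        is a global optimum of the joint likelihood, so the estimator relies
        on a local optimum anchored near the sources.
    tol : convergence threshold on the largest absolute change in any mixing
        proportion between successive iterations. The update to alpha rather
        than the joint log-likelihood is monitored because the likelihood is
        dominated by the (fixed-magnitude) source-count term, which makes a
        relative-likelihood criterion insensitive to the sink fit.
    n_restarts : independent alpha initializations (uniform, then jittered);
        the restart with the best final likelihood is returned.

    Returns the best :class:`MixtureEstimate`; its log-likelihood trace is
    non-decreasing (a property of EM on the joint model).
    """
    x = np.asarray(sink, dtype=float)
    if x.ndim != 1 or x.sum() <= 0:
        raise SourceTrackError("sink must be a 1-D count vector with positive total")
    names = list(sources)
    if not names:
        raise SourceTrackError("at least one source is required")
    source_counts = np.vstack([np.asarray(sources[n], dtype=float) for n in names])
    if source_counts.shape[1] != x.size:
        raise SourceTrackError("sources and sink must share one taxon universe")
    if np.any(source_counts.sum(axis=1) <= 0):
        raise SourceTrackError("every source needs a positive total")

    k_obs = len(names)
    k = k_obs + (1 if include_unknown else 0)
    padded = source_counts + SOURCE_PSEUDOCOUNT
    sink_present = x > 0

    if not include_unknown and not np.any(padded[:, sink_present].sum(axis=0) > 0):
        raise SourceTrackError("sink has no taxon with positive source probability")

    rng = np.random.default_rng(seed)
    best: MixtureEstimate | None = None
    for restart in range(n_restarts):
        alphas = np.full(k, 1.0 / k)
        if restart > 0:
            alphas = rng.dirichlet(np.full(k, 5.0))
        gammas = np.empty((k, x.size))
        gammas[:k_obs] = padded / padded.sum(axis=1, keepdims=True)
        if include_unknown:
            g_u = np.maximum(x / x.sum() - gammas[:k_obs].mean(axis=0), 0.0)
            if g_u.sum() == 0:
                g_u = np.where(sink_present, 1.0, 0.0)
            gammas[k_obs] = g_u / g_u.sum()
        trace = [_joint_loglik(x, padded, gammas, alphas)]
        converged = False
        for it in range(max_iter):
            mix = alphas @ gammas  # (n_taxa,)
            with np.errstate(divide="ignore", invalid="ignore"):
                resp = alphas[:, None] * gammas / mix[None, :]
            resp[:, ~sink_present] = 0.0
            resp = np.nan_to_num(resp, nan=0.0)
            assigned = resp * x[None, :]  # expected sink reads per source/taxon
            # M-step
            new_alphas = assigned.sum(axis=1)
            new_alphas = new_alphas / new_alphas.sum()
            alpha_delta = float(np.abs(new_alphas - alphas).max())
            alphas = new_alphas
            new_gamma = np.empty_like(gammas)
            new_gamma[:k_obs] = padded + assigned[:k_obs]
            if include_unknown:
                gu = assigned[k_obs]
                new_gamma[k_obs] = gu if gu.sum() > 0 else gammas[k_obs]
            gammas = new_gamma / new_gamma.sum(axis=1, keepdims=True)
            ll = _joint_loglik(x, padded, gammas, alphas)
            trace.append(ll)
            if not np.isfinite(ll):
                raise SourceTrackError("non-finite log-likelihood")
            if alpha_delta <= tol:
                converged = True
                break
        est = MixtureEstimate(
            sink_id=sink_id,
            source_names=names + ([UNKNOWN] if include_unknown else []),
            proportions=alphas,
            log_likelihood_trace=trace,
            n_iterations=len(trace) - 1,
            converged=converged,
        )
        if best is None or trace[-1] > best.log_likelihood_trace[-1]:
            best = est
    assert best is not None
    return best


def coalescence_extent(
    estimate: MixtureEstimate, source_class_map: Mapping[str, str]
) -> CoalescenceRecord:
    """Sum mixing proportions by source class (water vs sediment)."""
    water = sediment = unknown = 0.0
    for name, a in zip(estimate.source_names, estimate.proportions):
        if name == UNKNOWN:
            unknown += float(a)
            continue
        cls = source_class_map.get(name)
        if cls == "water":
            water += float(a)
        elif cls == "sediment":
            sediment += float(a)
        else:
            raise SourceTrackError(f"source {name!r} not mapped to water/sediment")
    if not estimate.source_names or UNKNOWN not in estimate.source_names:
        unknown = max(0.0, 1.0 - water - sediment)
    return CoalescenceRecord(estimate.sink_id, water, sediment, unknown)


def classify_habitat(record: CoalescenceRecord) -> str:
    """Pelagic if the gut coalesces more with water, benthic if with sediment."""
    return record.habitat_label


def track_study(
    table,
    meta,
    include_unknown: bool = True,
    rarefy_depth: int | None = None,
    seed: int = 0,
    **em_kwargs,
) -> tuple[list[MixtureEstimate], pd.DataFrame]:
    """Source-track every gut sample against all water/sediment samples.

    Each environmental sample enters as its own source; class totals are the
    sums over the water and sediment sources. Returns the per-sink estimates
    and a tidy coalescence table (water_total, sediment_total, unknown,
    habitat, low_confidence) indexed by sink.
    """
    from .tables import metadata_by_id, rarefy

    lookup = metadata_by_id(meta)
    gut_ids = [s for s in table.sample_ids if lookup[s].sample_class == "gut"]
    env_ids = [s for s in table.sample_ids if lookup[s].sample_class in ("water", "sediment")]
    if not gut_ids or not env_ids:
        raise SourceTrackError("need at least one gut sink and one environmental source")
    class_map = {s: lookup[s].sample_class for s in env_ids}
    rng = np.random.default_rng(seed)

    def _vec(sid: str) -> np.ndarray:
        v = table.sample_counts(sid)
        if rarefy_depth is not None:
            v = rarefy(v, rarefy_depth, rng)
        return v

    sources = {s: _vec(s) for s in env_ids}
    estimates, rows = [], []
    for sid in gut_ids:
        est = em_source_tracking(
            _vec(sid), sources, sink_id=sid, include_unknown=include_unknown,
            seed=seed, **em_kwargs,
        )
        rec = coalescence_extent(est, class_map)
        estimates.append(est)
        rows.append(
            {
                "sample_id": sid,
                "water_total": rec.water_total,
                "sediment_total": rec.sediment_total,
                "unknown": rec.unknown,
                "habitat": rec.habitat_label,
                "low_confidence": rec.low_confidence,
            }
        )
    return estimates, pd.DataFrame(rows).set_index("sample_id")
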