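"""Regular, Remove and Refit assignment strategies over any engine.

Given a catalog V and reference set W, every strategy first obtains a
full-reference per-sample fit from the chosen engine ("Regular").  They then
differ in how sub-threshold activities are treated:

* Regular — keep everything (optionally flooring trace activities and
  renormalizing); all mutations remain assigned.
* Remove  — zero signatures below the activity threshold and move their
  mass to the Unassigned pool; the retained activities are NOT renormalized,
  so mutation utilization drops below 1.
* Refit   — select the signatures at or above the threshold and re-run the
  engine restricted to that subset (optionally iterating until the subset is
  stable); all mutations are redistributed over the final subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engines import EngineSpec, fit_engine
from .formats import UNASSIGNED, ActivityMatrix, MutationalCatalog, SignatureSet
from .metrics import cosine_rvo

STRATEGY_NAMES = ("regular", "remove", "refit")


@dataclass(frozen=True)
class StrategySpec:
    """Configuration of one assignment strategy.

    ``activity_threshold`` is a proportion of each sample's assigned
    mutation mass (default 5%).  ``regular_floor`` emulates the trace-level
    floor some tools apply under Regular (e.g. 1e-4 for a 0.01% threshold).
    """

    name: str = "refit"
    activity_threshold: float = 0.05
    regular_floor: float = 0.0
    refit_mode: str = "single_pass"  # or "iterative"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}")
        if not 0.0 <= self.activity_threshold <= 1.0:
            raise ValueError("activity_threshold must lie in [0, 1]")
        if self.regular_floor > self.activity_threshold:
            raise ValueError("regular_floor must not exceed activity_threshold")
        if self.refit_mode not in ("single_pass", "iterative"):
            raise ValueError(f"unknown refit_mode {self.refit_mode!r}")


@dataclass
class AssignmentResult:
    """One engine-strategy run: activities plus reconstruction diagnostics."""

    engine: EngineSpec
    strategy: StrategySpec
    activities: ActivityMatrix
    reconstructed: pd.DataFrame  # 96 x N, count scale, retained signatures only
    rvo: pd.Series  # cosine(original, reconstructed); NaN when undefined
    removed_spectrum: pd.DataFrame  # 96 x N; nonzero only under Remove
    fallback_samples: list[str] = field(default_factory=list)

    @property
    def n_assigned_signatures(self) -> pd.Series:
        return self.activities.n_assigned()

    @property
    def unassigned_proportion(self) -> pd.Series:
        return self.activities.unassigned_proportion


def _engine_proportions(
    catalog: MutationalCatalog, signatures: SignatureSet, engine: EngineSpec
) -> pd.DataFrame:
    exposures = fit_engine(catalog.counts.to_numpy(), signatures, engine)
    P = np.column_stack([e.proportions for e in exposures])
    return pd.DataFrame(P, index=signatures.signature_ids, columns=catalog.sample_ids)


def _result(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    engine: EngineSpec,
    strategy: StrategySpec,
    assigned_props: pd.DataFrame,
    unassigned: pd.Series,
    removed_counts: pd.DataFrame | None = None,
    fallback: list[str] | None = None,
) -> AssignmentResult:
    burdens = catalog.burdens.astype(float)
    props = assigned_props.copy()
    props.loc[UNASSIGNED] = unassigned
    activities = ActivityMatrix.from_proportions(props, burdens)
    W = signatures.profiles
    retained_counts = activities.counts.loc[activities.signature_ids]
    recon = W.to_numpy() @ retained_counts.to_numpy()
    recon_df = pd.DataFrame(recon, index=W.index, columns=catalog.sample_ids)
    rvo = pd.Series(
        [
            cosine_rvo(catalog.counts.iloc[:, j].to_numpy(), recon[:, j])
            for j in range(recon.shape[1])
        ],
        index=catalog.sample_ids,
        dtype=float,
    )
    if removed_counts is None:
        removed_counts = pd.DataFrame(
            np.zeros_like(recon), index=W.index, columns=catalog.sample_ids
        )
    return AssignmentResult(
        engine=engine,
        strategy=strategy,
        activities=activities,
        reconstructed=recon_df,
        rvo=rvo,
        removed_spectrum=removed_counts,
        fallback_samples=fallback or [],
    )


def _apply_floor(P: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Zero proportions below ``floor`` and renormalize the remainder."""
    if floor <= 0:
        out = P.copy()
    else:
        out = P.where(P >= floor, 0.0)
        sums = out.sum(axis=0)
        # a column losing everything keeps its single largest activity
        dead = sums <= 0
        for s in out.columns[dead]:
            top = P[s].idxmax()
            out.loc[top, s] = 1.0
        sums = out.sum(axis=0)
        out = out / sums
    return out


def assign_regular(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    engine: EngineSpec | None = None,
    spec: StrategySpec | None = None,
) -> AssignmentResult:
    """Fit the full reference set; no mass is ever unassigned."""
    engine = engine or EngineSpec()
    spec = spec or StrategySpec(name="regular")
    P = _engine_proportions(catalog, signatures, engine)
    P = _apply_floor(P, spec.regular_floor)
    zeros = pd.Series(0.0, index=catalog.sample_ids)
    return _result(catalog, signatures, engine, spec, P, zeros)


def assign_remove(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    engine: EngineSpec | None = None,
    spec: StrategySpec | None = None,
) -> AssignmentResult:
    """Regular fit, then activities below the threshold become Unassigned.

    Retained proportions are deliberately not renormalized: the removed mass
    is reported in the Unassigned row and its spectrum (W times the removed
    activities, in counts) in ``removed_spectrum``.
    """
    engine = engine or EngineSpec()
    spec = spec or StrategySpec(name="remove")
    P = _engine_proportions(catalog, signatures, engine)
    P = _apply_floor(P, spec.regular_floor)
    retained = P.where(P >= spec.activity_threshold, 0.0)
    removed = P - retained
    unassigned = removed.sum(axis=0)
    removed_counts_H = removed * catalog.burdens.astype(float)
    removed_spec = pd.DataFrame(
        signatures.matrix @ removed_counts_H.to_numpy(),
        index=signatures.profiles.index,
        columns=catalog.sample_ids,
    )
    return _result(catalog, signatures, engine, spec, retained, unassigned, removed_spec)


def assign_refit(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    engine: EngineSpec | None = None,
    spec: StrategySpec | None = None,
) -> AssignmentResult:
    """Regular fit, subset to >=threshold signatures, re-fit on the subset.

    In ``iterative`` mode the subset step repeats until the retained set is
    stable or a single signature remains.  If no signature reaches the
    threshold the single highest-activity signature is kept and the sample
    recorded in ``fallback_samples``.
    """
    engine = engine or EngineSpec()
    spec = spec or StrategySpec(name="refit")
    P = _engine_proportions(catalog, signatures, engine)
    all_ids = signatures.signature_ids
    out = pd.DataFrame(0.0, index=all_ids, columns=catalog.sample_ids)
    fallback: list[str] = []
    V = catalog.counts
    for s in catalog.sample_ids:
        p = P[s]
        keep = list(p.index[p >= spec.activity_threshold])
        if not keep:
            keep = [p.idxmax()]
            fallback.append(s)
        v = V[s].to_numpy()
        for _ in range(len(all_ids)):
            sub = signatures.subset(keep)
            exp = fit_engine(v, sub, engine)[0]
            p_sub = pd.Series(exp.proportions, index=keep)
            if spec.refit_mode == "single_pass" or len(keep) == 1:
                break
            keep_next = list(p_sub.index[p_sub >= spec.activity_threshold])
            if not keep_next:
                keep_next = [p_sub.idxmax()]
            if set(keep_next) == set(keep):
                break
            keep = keep_next
        out.loc[p_sub.index, s] = p_sub
    sums = out.sum(axis=0)
    out = out / sums.where(sums > 0, 1.0)
    zeros = pd.Series(0.0, index=catalog.sample_ids)
    return _result(catalog, signatures, engine, spec, out, zeros, fallback=fallback)


def assign(
    catalog: MutationalCatalog,
    signatures: SignatureSet,
    engine: EngineSpec | None = None,
    spec: StrategySpec | None = None,
) -> AssignmentResult:
    """Dispatch on ``spec.name``; defaults to Refit with the NNLS engine."""
    spec = spec or StrategySpec()
    fn = {"regular": assign_regular, "remove": assign_remove, "refit": assign_refit}[
        spec.name
    ]
    return fn(catalog, signatures, engine, spec)


def summarize_strategy(result: AssignmentResult) -> pd.DataFrame:
    """Per-sample table of the three headline assignment metrics."""
    return pd.DataFrame(
        {
            "n_assigned": result.n_assigned_signatures,
            "utilization": 1.0 - result.unassigned_proportion,
            "rvo": result.rvo,
        }
    )
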