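"""Consensus integration of multiple activity matrices.

Given M aligned members (different engines, or external tools' activity
files ingested through :func:`sigensemble.formats.read_activities`), three
consensus models are available:

* Majority  — a signature is present in a sample when more than half the
  members assign it positive activity (>= 3 of 5 for five members);
* Unanimous — present only when every member assigns it;
* Mean      — per signature and sample, bootstrap resampling of means
  (default n = 500) across the member proportions, averaged and then
  column-standardized so each sample's proportions sum to 1.

The Unassigned row never votes and is excluded from the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import UNASSIGNED, ActivityMatrix


@dataclass
class EnsembleInput:
    members: list[ActivityMatrix]
    member_names: list[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least two members")
        if len(self.member_names) != len(self.members):
            raise ValueError("one name per member required")
        sig0 = self.members[0].signature_ids
        smp0 = self.members[0].sample_ids
        problems = []
        for name, m in zip(self.member_names, self.members):
            if m.signature_ids != sig0:
                problems.append(f"{name}: signature ids differ")
            if m.sample_ids != smp0:
                problems.append(f"{name}: sample ids differ")
        if problems:
            raise ValueError("misaligned members: " + "; ".join(problems))

    @property
    def signature_ids(self) -> list[str]:
        return self.members[0].signature_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.members[0].sample_ids


@dataclass
class EnsembleResult:
    presence_majority: pd.DataFrame
    presence_unanimous: pd.DataFrame
    mean_activities: ActivityMatrix
    vote_counts: pd.DataFrame
    n_resamples: int
    seed: int


def align_members(
    members: list[ActivityMatrix], names: list[str] | None = None
) -> EnsembleInput:
    """Align raw members onto the union of signatures and the intersection
    of samples; signatures absent from a member count as zero activity."""
    if len(members) < 2:
        raise ValueError("an ensemble needs at least two members")
    names = names or [f"member{i + 1}" for i in range(len(members))]
    sig_union: list[str] = []
    for m in members:
        for s in m.signature_ids:
            if s not in sig_union:
                sig_union.append(s)
    common = set(members[0].sample_ids)
    for m in members[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all members")
    sample_order = [s for s in members[0].sample_ids if s in common]
    dropped = {
        name: sorted(set(m.sample_ids) - common) for name, m in zip(names, members)
    }
    dropped = {k: v for k, v in dropped.items() if v}
    if dropped:
        warnings.warn(f"samples dropped during alignment: {dropped}", stacklevel=2)
    aligned = []
    for m in members:
        props = m.proportions.reindex(index=sig_union + [UNASSIGNED], fill_value=0.0)
        cnts = m.counts.reindex(index=sig_union + [UNASSIGNED], fill_value=0.0)
        aligned.append(
            ActivityMatrix(proportions=props[sample_order], counts=cnts[sample_order])
        )
    return EnsembleInput(members=aligned, member_names=names)


def vote_counts(inp: EnsembleInput) -> pd.DataFrame:
    """Number of members assigning positive activity, per signature/sample."""
    stack = np.stack([m.assigned_proportions.to_numpy() > 0 for m in inp.members])
    return pd.DataFrame(
        stack.sum(axis=0), index=inp.signature_ids, columns=inp.sample_ids
    )


def ensemble_majority(inp: EnsembleInput) -> pd.DataFrame:
    """Present iff assigned by a strict majority of members (>=3 of 5)."""
    votes = vote_counts(inp)
    return votes > len(inp.members) / 2


def ensemble_unanimous(inp: EnsembleInput) -> pd.DataFrame:
    """Present iff every member assigns positive activity."""
    votes = vote_counts(inp)
    return votes == len(inp.members)


def ensemble_mean(
    inp: EnsembleInput, n_resamples: int = 500, seed: int = 0
) -> ActivityMatrix:
    """Bootstrap-mean consensus activities.

    For each signature/sample cell, draw ``n_resamples`` bootstrap samples
    of size M with replacement from the M member proportions, average each,
    and take the mean of those bootstrap means; the per-sample vector is
    then standardized to sum to 1.  Deterministic for a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    M = len(inp.members)
    vals = np.stack([m.assigned_proportions.to_numpy() for m in inp.members])  # M,K,N
    rng = np.random.default_rng(seed)
    acc = np.zeros(vals.shape[1:])
    for _ in range(n_resamples):
        idx = rng.integers(0, M, size=M)
        acc += vals[idx].mean(axis=0)
    est = acc / n_resamples
    sums = est.sum(axis=0)
    ok = sums > 0
    est[:, ok] = est[:, ok] / sums[ok]
    props = pd.DataFrame(est, index=inp.signature_ids, columns=inp.sample_ids)
    props.loc[UNASSIGNED] = np.where(ok, 0.0, 1.0)
    burdens = inp.members[0].counts.sum(axis=0)
    return ActivityMatrix.from_proportions(props, burdens)


def plain_mean(inp: EnsembleInput) -> ActivityMatrix:
    """Arithmetic across-member mean (the n -> infinity bootstrap limit)."""
    vals = np.stack([m.assigned_proportions.to_numpy() for m in inp.members])
    est = vals.mean(axis=0)
    sums = est.sum(axis=0)
    ok = sums > 0
    est[:, ok] = est[:, ok] / sums[ok]
    props = pd.DataFrame(est, index=inp.signature_ids, columns=inp.sample_ids)
    props.loc[UNASSIGNED] = np.where(ok, 0.0, 1.0)
    burdens = inp.members[0].counts.sum(axis=0)
    return ActivityMatrix.from_proportions(props, burdens)


def run_ensemble(
    inp: EnsembleInput, n_resamples: int = 500, seed: int = 0
) -> EnsembleResult:
    return EnsembleResult(
        presence_majority=ensemble_majority(inp),
        presence_unanimous=ensemble_unanimous(inp),
        mean_activities=ensemble_mean(inp, n_resamples=n_resamples, seed=seed),
        vote_counts=vote_counts(inp),
        n_resamples=n_resamples,
        seed=seed,
    )
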