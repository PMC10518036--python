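"""Evaluation statistics for signature assignment.

Covers reconstruction similarity (RvO cosine), qualitative agreement
(Jaccard), quantitative concordance (tie-corrected Kendall tau-b with
sample- and signature-level validity rules), profile flatness (Shannon
diversity), accuracy against simulated truth (pooled RMSE on active
entries), confusion-matrix diagnostics, and dominant-signature consensus.
Missing values propagate as NaN and are excluded from means; exclusion
counts are reported where they matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .formats import ActivityMatrix


def cosine_rvo(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """Cosine similarity between an observed spectrum and its reconstruction.

    In [0, 1] for non-negative inputs; scale-invariant.  NaN if either
    vector is all-zero.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(reconstructed, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.dot(a, b) / (na * nb))


def jaccard(a: set, b: set) -> float:
    """|A intersect B| / |A union B|; NaN when both sets are empty."""
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation.

    tau_b = (C - D) / sqrt((C + D + Tx)(C + D + Ty)) where C/D count
    concordant/discordant pairs and Tx/Ty pairs tied only in x / only in y.
    NaN when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 2:
        return float("nan")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = scipy.stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def shannon_diversity(profile) -> float:
    """Shannon diversity index -sum p ln p (natural log), a flatness score.

    0 for a one-hot profile, ln(96) ~ 4.564 for a uniform SBS96 profile.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("profile entries must be non-negative")
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError("profile must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def rmse_vs_truth(estimated: ActivityMatrix, truth: ActivityMatrix) -> float:
    """Pooled RMSE over the entries where the truth activity is positive.

    Only the signatures actually active in the simulated truth count toward
    the error; all samples pool into a single cohort value.
    """
    sig_ids = [s for s in truth.signature_ids]
    est = estimated.assigned_proportions.reindex(index=sig_ids, fill_value=0.0)
    est = est[truth.sample_ids]
    t = truth.assigned_proportions
    mask = t.to_numpy() > 0
    if not mask.any():
        raise ValueError("truth has no active entries")
    diff = est.to_numpy()[mask] - t.to_numpy()[mask]
    return float(np.sqrt(np.mean(diff**2)))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")


def confusion_rates(c: ConfusionCounts) -> dict[str, float]:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/total.

    A zero denominator yields NaN for that rate.
    """
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    npv = c.tn / (c.tn + c.fn) if (c.tn + c.fn) else float("nan")
    acc = (c.tp + c.tn) / (c.tp + c.fp + c.tn + c.fn)
    return {"ppv": ppv, "npv": npv, "accuracy": acc}


def binary_confusion(predicted_present, truth_present) -> ConfusionCounts:
    """Tally a qualitative call (e.g. SBS3 present) against truth labels."""
    pred = np.asarray(predicted_present, dtype=bool)
    truth = np.asarray(truth_present, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


# ---------------------------------------------------------------------------
# concordance across members (tools / engines)


@dataclass
class ConcordanceReport:
    pairwise_jaccard: pd.DataFrame  # M x M, mean per-sample Jaccard
    pairwise_tau: pd.DataFrame  # M x M, mean per-sample tau-b
    per_signature_tau: pd.Series  # mean over member pairs, valid signatures
    per_signature_sdi: pd.Series | None
    valid_sample_ids: list[str]
    valid_signature_ids: list[str]
    n_excluded: dict[str, int] | None = None


def _check_aligned(members: list[ActivityMatrix]) -> tuple[list[str], list[str]]:
    if len(members) < 2:
        raise ValueError("need at least two members")
    sig_ids = members[0].signature_ids
    sample_ids = members[0].sample_ids
    for m in members[1:]:
        if m.signature_ids != sig_ids or m.sample_ids != sample_ids:
            raise ValueError("members are not aligned; run align_members first")
    return sig_ids, sample_ids


def samplewise_concordance(
    members: list[ActivityMatrix], names: list[str] | None = None
) -> ConcordanceReport:
    """Per-pair mean Jaccard and Kendall tau-b across valid samples.

    A sample is valid only if every member assigns it at least two
    signatures, so each pairwise correlation is computable everywhere.
    Within a pair and sample, signatures assigned zero by both members are
    dropped before correlating; per-sample Jaccard compares the sets of
    signatures with positive activity.
    """
    sig_ids, sample_ids = _check_aligned(members)
    M = len(members)
    names = names or [f"member{i + 1}" for i in range(M)]
    n_assigned = pd.DataFrame(
        {i: m.n_assigned() for i, m in enumerate(members)}
    )
    valid = n_assigned.min(axis=1) >= 2
    valid_samples = [s for s in sample_ids if valid[s]]
    if not valid_samples:
        raise ValueError("no valid samples (every sample has <2 signatures somewhere)")
    J = pd.DataFrame(np.eye(M), index=names, columns=names)
    T = pd.DataFrame(np.eye(M), index=names, columns=names)
    dropped_tau = 0
    props = [m.assigned_proportions[valid_samples] for m in members]
    for i, j in combinations(range(M), 2):
        taus, jacs = [], []
        for s in valid_samples:
            xi = props[i][s].to_numpy()
            xj = props[j][s].to_numpy()
            keep = (xi > 0) | (xj > 0)
            tau = kendall_tau_b(xi[keep], xj[keep]) if keep.sum() >= 2 else float("nan")
            if np.isnan(tau):
                dropped_tau += 1
            else:
                taus.append(tau)
            set_i = {sig_ids[k] for k in np.flatnonzero(xi > 0)}
            set_j = {sig_ids[k] for k in np.flatnonzero(xj > 0)}
            jacs.append(jaccard(set_i, set_j))
        J.iloc[i, j] = J.iloc[j, i] = float(np.nanmean(jacs))
        T.iloc[i, j] = T.iloc[j, i] = float(np.mean(taus)) if taus else float("nan")
    return ConcordanceReport(
        pairwise_jaccard=J,
        pairwise_tau=T,
        per_signature_tau=pd.Series(dtype=float),
        per_signature_sdi=None,
        valid_sample_ids=valid_samples,
        valid_signature_ids=[],
        n_excluded={"tau_undefined_sample_pairs": dropped_tau},
    )


def signaturewise_concordance(
    members: list[ActivityMatrix],
    names: list[str] | None = None,
    signatures=None,
) -> ConcordanceReport:
    """Mean per-signature tau-b across all member pairs.

    For a member pair, a signature is valid when at least two samples have
    positive activity from at least one of the two members; samples where
    both assign zero are excluded from the correlation.  A signature must be
    valid for every pair to receive a score; invalid signatures are reported
    separately.  When a :class:`SignatureSet` is supplied, each signature's
    Shannon diversity (flatness) is attached.
    """
    sig_ids, sample_ids = _check_aligned(members)
    M = len(members)
    names = names or [f"member{i + 1}" for i in range(M)]
    props = [m.assigned_proportions for m in members]
    pair_taus: dict[str, list[float]] = {k: [] for k in sig_ids}
    invalid: set[str] = set()
    for i, j in combinations(range(M), 2):
        Pi, Pj = props[i].to_numpy(), props[j].to_numpy()
        for k, sig in enumerate(sig_ids):
            xi, xj = Pi[k], Pj[k]
            keep = (xi > 0) | (xj > 0)
            if keep.sum() < 2:
                invalid.add(sig)
                continue
            pair_taus[sig].append(kendall_tau_b(xi[keep], xj[keep]))
    valid_sigs = [s for s in sig_ids if s not in invalid]
    per_sig = pd.Series(
        {s: float(np.nanmean(pair_taus[s])) if pair_taus[s] else float("nan") for s in valid_sigs},
        dtype=float,
    )
    sdi = None
    if signatures is not None:
        sdi = pd.Series(
            {
                s: shannon_diversity(signatures.profiles[s].to_numpy())
                for s in sig_ids
                if s in signatures.profiles.columns
            },
            dtype=float,
        )
    return ConcordanceReport(
        pairwise_jaccard=pd.DataFrame(),
        pairwise_tau=pd.DataFrame(),
        per_signature_tau=per_sig,
        per_signature_sdi=sdi,
        valid_sample_ids=list(sample_ids),
        valid_signature_ids=valid_sigs,
    )


# ---------------------------------------------------------------------------
# dominant signatures


def dominant_signature(activities: ActivityMatrix) -> pd.DataFrame:
    """Per-sample highest-activity signature (Unassigned excluded).

    Ties break lexicographically on the signature id and are flagged; a
    sample with no positive activity gets a missing value.
    """
    props = activities.assigned_proportions
    out = []
    for s in activities.sample_ids:
        col = props[s]
        top = col.max()
        if top <= 0:
            out.append((s, None, False))
            continue
        winners = sorted(col.index[col == top])
        out.append((s, winners[0], len(winners) > 1))
    return pd.DataFrame(out, columns=["sample_id", "dominant", "tie"]).set_index(
        "sample_id"
    )


def dominant_consensus(members: list[ActivityMatrix]) -> pd.DataFrame:
    """How many members agree on each sample's modal dominant signature."""
    _check_aligned(members)
    doms = [dominant_signature(m)["dominant"] for m in members]
    table = pd.concat(doms, axis=1)
    rows = []
    for s, row in table.iterrows():
        vals = [v for v in row if v is not None]
        if not vals:
            rows.append((s, None, 0))
            continue
        counts = pd.Series(vals).value_counts()
        modal = sorted(counts.index[counts == counts.max()])[0]
        rows.append((s, modal, int(counts.max())))
    return pd.DataFrame(rows, columns=["sample_id", "modal_dominant", "consensus"]).set_index("sample_id")
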