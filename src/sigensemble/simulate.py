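"""Synthetic cohort generation for ground-truth benchmarking.

Builds synthetic signature sets (spiky and flat profiles), ground-truth
activity matrices and SBS96 catalogs so that assignment and ensembling can
be validated against a known truth without any external data.  The sampling
scheme is a parametric surrogate for activity-resampling simulators: each
sample carries a subset of signatures drawn by per-signature prevalence,
carrier magnitudes drawn from a gamma law and normalized to the simplex,
and a total burden drawn log-uniformly; the catalog is then multinomial (or
Poisson) noise around burden x W h.  All randomness flows from one cohort
seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import CANONICAL_LABELS
from .formats import ActivityMatrix, MutationalCatalog, SignatureSet


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``prevalence`` is the probability each signature is active in a sample
    (minimum two carriers are enforced per sample); ``activity_shape`` is
    the gamma shape of carrier magnitudes before simplex normalization
    (shape < 1 yields many small, sub-threshold activities); burdens are
    log-uniform over ``burden_range`` mutations per sample.
    """

    n_samples: int = 100
    prevalence: float = 0.5
    activity_shape: float = 1.5
    burden_range: tuple[int, int] = (1_000, 50_000)
    min_carriers: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in (0, 1]")
        if self.burden_range[0] < 100 or self.burden_range[1] < self.burden_range[0]:
            raise ValueError("burdens must be >= 100 and the range ordered")
        if self.n_samples < 1 or self.min_carriers < 1:
            raise ValueError("n_samples and min_carriers must be positive")


@dataclass
class SyntheticTruth:
    """A simulated catalog paired with the activities that generated it."""

    signatures: SignatureSet
    activities: ActivityMatrix  # truth proportions, Unassigned = 0
    burdens: pd.Series
    catalog: MutationalCatalog
    seed: int
    noise_model: str = "multinomial"


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


def make_signatures(
    k: int,
    flat_fraction: float = 0.0,
    seed: int = 0,
    max_pairwise_cosine: float = 0.9,
    max_retries: int = 2_000,
) -> SignatureSet:
    """Generate k synthetic SBS96 profiles, a mix of spiky and flat.

    Spiky profiles concentrate their mass on 3-8 channels (low Shannon
    diversity); flat profiles are mild Dirichlet perturbations of the
    uniform profile (diversity near ln 96).  Pairwise cosine similarity
    below ``max_pairwise_cosine`` is enforced by rejection sampling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= flat_fraction <= 1.0:
        raise ValueError("flat_fraction must lie in [0, 1]")
    rng = _rng_for(seed, 0)
    n_flat = int(round(k * flat_fraction))
    cols: list[np.ndarray] = []
    kinds = ["flat"] * n_flat + ["spiky"] * (k - n_flat)
    for kind in kinds:
        for attempt in range(max_retries):
            if kind == "flat":
                # alpha=2 keeps mass on every channel (SDI ~ 4.3 of ln 96
                # ~ 4.56) while typical pairwise cosines stay well below 0.9
                p = rng.dirichlet(np.full(96, 2.0))
            else:
                n_active = rng.integers(3, 9)
                idx = rng.choice(96, size=n_active, replace=False)
                p = np.zeros(96)
                p[idx] = rng.dirichlet(np.ones(n_active))
            if all(
                float(p @ q) / (np.linalg.norm(p) * np.linalg.norm(q))
                < max_pairwise_cosine
                for q in cols
            ):
                cols.append(p)
                break
        else:
            raise RuntimeError(
                f"could not draw signature {len(cols) + 1} with pairwise "
                f"cosine < {max_pairwise_cosine} in {max_retries} tries"
            )
    names = [f"SYN{i + 1}" for i in range(k)]
    df = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(CANONICAL_LABELS, name="Type"), columns=names
    )
    return SignatureSet(df)


def make_activities(
    spec: CohortSpec, signatures: SignatureSet, seed: int = 0
) -> tuple[ActivityMatrix, pd.Series]:
    """Draw ground-truth activities and burdens for a cohort.

    Per sample: carriers by independent Bernoulli(prevalence) with at least
    ``min_carriers`` enforced by topping up uniformly at random; carrier
    magnitudes ~ Gamma(activity_shape, 1) normalized to sum to 1; burden
    log-uniform over ``burden_range``.
    """
    rng = _rng_for(seed, 1)
    k = signatures.n_signatures
    sig_ids = signatures.signature_ids
    min_carriers = min(spec.min_carriers, k)
    props = np.zeros((k, spec.n_samples))
    for j in range(spec.n_samples):
        carriers = np.flatnonzero(rng.random(k) < spec.prevalence)
        if carriers.size < min_carriers:
            extra = rng.choice(
                np.setdiff1d(np.arange(k), carriers),
                size=min_carriers - carriers.size,
                replace=False,
            )
            carriers = np.concatenate([carriers, extra])
        mags = rng.gamma(spec.activity_shape, 1.0, size=carriers.size)
        while mags.sum() <= 0:  # all-zero draw is measure-zero but guard anyway
            mags = rng.gamma(spec.activity_shape, 1.0, size=carriers.size)
        props[carriers, j] = mags / mags.sum()
    lo, hi = spec.burden_range
    burdens = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_samples))
    burdens = np.round(burdens).astype(int)
    samples = [f"SAMPLE{j + 1}" for j in range(spec.n_samples)]
    props_df = pd.DataFrame(props, index=sig_ids, columns=samples)
    burdens_s = pd.Series(burdens, index=samples, name="burden")
    return ActivityMatrix.from_proportions(props_df, burdens_s), burdens_s


def make_catalog(
    activities: ActivityMatrix,
    signatures: SignatureSet,
    burdens: pd.Series,
    noise_model: str = "multinomial",
    seed: int = 0,
) -> MutationalCatalog:
    """Sample a catalog around the expected spectra burden x W h.

    ``multinomial`` conserves each sample's burden exactly; ``poisson``
    draws channel counts independently; ``none`` rounds the expectation.
    """
    if noise_model not in ("multinomial", "poisson", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = _rng_for(seed, 2)
    W = signatures.matrix
    H = activities.assigned_proportions.reindex(signatures.signature_ids).to_numpy()
    samples = activities.sample_ids
    burdens = pd.Series(burdens, index=samples)
    if (burdens <= 0).any():
        raise ValueError("all burdens must be positive")
    counts = np.zeros((96, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        p = W @ H[:, j]
        p = np.maximum(p, 0.0)
        p = p / p.sum()
        b = int(burdens.iloc[j])
        if noise_model == "multinomial":
            counts[:, j] = rng.multinomial(b, p)
        elif noise_model == "poisson":
            counts[:, j] = rng.poisson(b * p)
        else:
            counts[:, j] = np.round(b * p).astype(np.int64)
    df = pd.DataFrame(
        counts, index=pd.Index(CANONICAL_LABELS, name="MutationType"), columns=samples
    )
    return MutationalCatalog(df)


def simulate_cohort(
    spec: CohortSpec,
    k: int = 6,
    flat_fraction: float = 0.0,
    noise_model: str = "multinomial",
    seed: int = 0,
    signatures: SignatureSet | None = None,
) -> SyntheticTruth:
    """One-call cohort generation: signatures + truth activities + catalog."""
    sigs = signatures if signatures is not None else make_signatures(k, flat_fraction, seed)
    activities, burdens = make_activities(spec, sigs, seed)
    catalog = make_catalog(activities, sigs, burdens, noise_model, seed)
    return SyntheticTruth(
        signatures=sigs,
        activities=activities,
        burdens=burdens,
        catalog=catalog,
        seed=seed,
        noise_model=noise_model,
    )


def resample_from_reference(
    activities: ActivityMatrix,
    signatures: SignatureSet,
    seed: int = 0,
    n_samples: int | None = None,
    noise_model: str = "multinomial",
) -> SyntheticTruth:
    """Build a synthetic cohort from an externally supplied activity matrix.

    With ``n_samples=None`` the supplied activities are used verbatim as
    truth (preserving the source cohort's heterogeneity); otherwise samples
    are bootstrap-resampled with replacement from its columns.
    """
    missing = [s for s in activities.signature_ids if s not in signatures.signature_ids]
    if missing:
        raise ValueError(f"activity signatures absent from the reference set: {missing}")
    rng = _rng_for(seed, 3)
    props = activities.assigned_proportions
    burdens = activities.counts.sum(axis=0)
    if n_samples is not None:
        pick = rng.integers(0, props.shape[1], size=n_samples)
        names = [f"RESAMPLE{i + 1}" for i in range(n_samples)]
        props = pd.DataFrame(
            props.to_numpy()[:, pick], index=props.index, columns=names
        )
        burdens = pd.Series(burdens.to_numpy()[pick], index=names)
    sums = props.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError("reference activities contain empty samples")
    props = props / sums
    truth = ActivityMatrix.from_proportions(props, burdens)
    sub = signatures.subset(truth.signature_ids)
    catalog = make_catalog(truth, sub, pd.Series(burdens), noise_model, seed)
    return SyntheticTruth(
        signatures=sub,
        activities=truth,
        burdens=pd.Series(burdens),
        catalog=catalog,
        seed=seed,
        noise_model=noise_model,
    )
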