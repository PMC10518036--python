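"""Containers and plain-text I/O for catalogs, signature sets and activities.

All on-disk formats are tab-separated UTF-8 matrices.  Catalogs and
signature sets have the 96 channel labels in the first column; readers
reorder rows by label so any dialect's row order is accepted.  Activity
files are written in count scale with an ``Unassigned`` row always present;
column sums therefore carry the per-sample mutation burden, and proportions
are recovered exactly by column normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CANONICAL_LABELS, Sbs96Channel

UNASSIGNED = "Unassigned"

__all__ = [
    "UNASSIGNED",
    "MutationalCatalog",
    "SignatureSet",
    "ActivityMatrix",
    "CatalogFormatError",
    "read_catalog",
    "write_catalog",
    "read_signatures",
    "write_signatures",
    "read_activities",
    "write_activities",
    "build_catalog_from_vcf",
]


class CatalogFormatError(ValueError):
    """Raised for structurally invalid catalog / signature / activity files."""


def _validate_channel_index(index: Iterable[str], what: str) -> list[str]:
    labels = [str(x) for x in index]
    parsed = []
    for lab in labels:
        try:
            parsed.append(Sbs96Channel.parse(lab).label)
        except ValueError as e:
            raise CatalogFormatError(f"{what}: {e}") from None
    seen: set[str] = set()
    dups = sorted({lab for lab in parsed if lab in seen or seen.add(lab)})
    if dups:
        raise CatalogFormatError(f"{what}: duplicated channel labels {dups}")
    missing = sorted(set(CANONICAL_LABELS) - set(parsed))
    if missing:
        raise CatalogFormatError(
            f"{what}: {len(missing)} channel(s) missing: {missing}"
        )
    return parsed


@dataclass
class MutationalCatalog:
    """Observed SBS96 mutation counts, 96 channels x N samples (matrix V)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        labels = _validate_channel_index(self.counts.index, "catalog")
        df = self.counts.copy()
        df.index = pd.Index(labels, name="MutationType")
        df = df.reindex(list(CANONICAL_LABELS))
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(arr))
            raise CatalogFormatError(f"catalog: non-numeric entries at {bad[:5]}")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise CatalogFormatError(
                f"catalog: negative count at channel {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise CatalogFormatError(
                f"catalog: non-integral count at channel {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        if df.columns.duplicated().any():
            raise CatalogFormatError("catalog: duplicated sample ids")
        self.counts = df.astype(np.int64)

    @property
    def channels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    @property
    def burdens(self) -> pd.Series:
        """Per-sample total mutation count (column sums of V)."""
        return self.counts.sum(axis=0)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class SignatureSet:
    """Reference signature profiles, 96 channels x K column-stochastic (matrix W)."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        labels = _validate_channel_index(self.profiles.index, "signatures")
        df = self.profiles.astype(float).copy()
        df.index = pd.Index(labels, name="MutationType")
        df = df.reindex(list(CANONICAL_LABELS))
        if (df.to_numpy() < 0).any():
            raise CatalogFormatError("signatures: negative profile entries")
        sums = df.sum(axis=0)
        zero = [str(s) for s in sums.index[sums <= 0]]
        if zero:
            raise CatalogFormatError(f"signatures: zero-sum column(s) {zero}")
        if df.columns.duplicated().any():
            raise CatalogFormatError("signatures: duplicated signature ids")
        self.profiles = df / sums

    @property
    def signature_ids(self) -> list[str]:
        return [str(c) for c in self.profiles.columns]

    @property
    def n_signatures(self) -> int:
        return self.profiles.shape[1]

    def subset(self, ids: Sequence[str]) -> "SignatureSet":
        missing = [i for i in ids if i not in self.profiles.columns]
        if missing:
            raise KeyError(f"signature id(s) not in set: {missing}")
        return SignatureSet(self.profiles[list(ids)])

    @property
    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy()


@dataclass
class ActivityMatrix:
    """Signature activities per sample (matrix H) plus an Unassigned row.

    Holds both views of the same assignment: ``proportions`` columns sum to 1
    (the Unassigned row absorbs any removed mass) and ``counts`` columns sum
    to the catalog burden of each sample.
    """

    proportions: pd.DataFrame
    counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        props = self.proportions.astype(float).copy()
        if UNASSIGNED not in props.index:
            props.loc[UNASSIGNED] = 0.0
        # keep Unassigned as the last row
        sig_rows = [r for r in props.index if r != UNASSIGNED]
        props = props.loc[sig_rows + [UNASSIGNED]]
        arr = props.to_numpy()
        if (arr < -1e-12).any():
            raise ValueError("activity proportions must be non-negative")
        colsums = arr.sum(axis=0)
        bad = np.abs(colsums - 1.0) > 1e-6
        if bad.any():
            raise ValueError(
                f"activity proportion columns must sum to 1; offending samples "
                f"{[str(c) for c in props.columns[bad]]}"
            )
        self.proportions = props.clip(lower=0.0)
        if self.counts is None:
            self.counts = self.proportions.copy()
        else:
            cnts = self.counts.astype(float).copy()
            if UNASSIGNED not in cnts.index:
                cnts.loc[UNASSIGNED] = 0.0
            self.counts = cnts.loc[sig_rows + [UNASSIGNED]].clip(lower=0.0)
        if list(self.counts.columns) != list(self.proportions.columns):
            raise ValueError("counts and proportions sample ids disagree")

    @classmethod
    def from_proportions(
        cls, proportions: pd.DataFrame, burdens: pd.Series | np.ndarray | None = None
    ) -> "ActivityMatrix":
        """Build from a proportions table; counts are proportions x burden."""
        props = proportions.astype(float).copy()
        if UNASSIGNED not in props.index:
            props.loc[UNASSIGNED] = 0.0
        if burdens is None:
            burdens = pd.Series(1.0, index=props.columns)
        burdens = pd.Series(np.asarray(burdens, dtype=float), index=props.columns)
        return cls(proportions=props, counts=props * burdens)

    @property
    def signature_ids(self) -> list[str]:
        return [str(r) for r in self.proportions.index if r != UNASSIGNED]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.proportions.columns]

    @property
    def assigned_proportions(self) -> pd.DataFrame:
        """Proportions without the Unassigned row."""
        return self.proportions.loc[self.signature_ids]

    @property
    def unassigned_proportion(self) -> pd.Series:
        return self.proportions.loc[UNASSIGNED]

    def n_assigned(self) -> pd.Series:
        """Number of signatures with strictly positive proportion, per sample."""
        return (self.assigned_proportions > 0).sum(axis=0)


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    if df.shape[1] == 0:
        raise CatalogFormatError(f"{path}: no sample columns found")
    return df


def read_catalog(path: str | Path) -> MutationalCatalog:
    """Read a tab-separated SBS96 catalog; rows reordered by channel label."""
    df = _read_matrix(path)
    non_num = df.apply(pd.to_numeric, errors="coerce")
    if non_num.isna().any().any():
        r, c = np.argwhere(non_num.isna().to_numpy())[0]
        raise CatalogFormatError(
            f"{path}: non-numeric count at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return MutationalCatalog(non_num)


def write_catalog(catalog: MutationalCatalog, path: str | Path) -> None:
    catalog.counts.to_csv(path, sep="\t")


def read_signatures(
    path: str | Path, ids: Sequence[str] | None = None
) -> SignatureSet:
    """Read a COSMIC-style signature matrix, optionally subsetting by id.

    Columns are renormalized to sum to one at load time; the subset preserves
    the requested id order.
    """
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first not in ("Type", "MutationType") and not first.startswith("Unnamed"):
        # tolerate an unlabeled first column or any label: treat it as channels
        pass
    df = df.set_index(first)
    sigs = SignatureSet(df.apply(pd.to_numeric))
    if ids is not None:
        sigs = sigs.subset(list(ids))
    return sigs


def write_signatures(signatures: SignatureSet, path: str | Path) -> None:
    df = signatures.profiles.copy()
    df.index.name = "Type"
    df.to_csv(path, sep="\t")


def write_activities(activities: ActivityMatrix, path: str | Path) -> None:
    """Write an activity matrix in count scale (Unassigned row included)."""
    activities.counts.to_csv(path, sep="\t", float_format="%.12g", index_label="Signature")


def read_activities(
    path: str | Path, scale: str = "auto", strict: bool = False
) -> ActivityMatrix:
    """Read an activity matrix written by :func:`write_activities` or by an
    external tool.

    ``scale='count'`` treats values as mutation counts (column sums are the
    burdens); ``scale='proportion'`` expects columns summing to 1 and warns
    and renormalizes (or raises, under ``strict``) when a column is off by
    more than 1e-4; ``'auto'`` picks ``proportion`` when every column sum is
    below 1.5.  A missing Unassigned row is inserted as zeros.
    """
    if scale not in ("auto", "count", "proportion"):
        raise ValueError(f"unknown scale {scale!r}")
    df = _read_matrix(path).apply(pd.to_numeric)
    colsums = df.sum(axis=0)
    if (colsums <= 0).any():
        raise CatalogFormatError(f"{path}: sample column(s) with zero total activity")
    if scale == "auto":
        scale = "proportion" if float(colsums.max()) <= 1.5 else "count"
    if scale == "proportion":
        off = np.abs(colsums - 1.0) > 1e-4
        if off.any():
            msg = (
                f"{path}: proportion column(s) not summing to 1 within 1e-4: "
                f"{[str(c) for c in df.columns[off]]}"
            )
            if strict:
                raise CatalogFormatError(msg)
            warnings.warn(msg + "; renormalizing", stacklevel=2)
        burdens = pd.Series(1.0, index=df.columns)
    else:
        burdens = colsums
    props = df / colsums
    return ActivityMatrix.from_proportions(props, burdens)


# ---------------------------------------------------------------------------
# VCF -> catalog


@dataclass
class SkipRecord:
    contig: str
    pos: int
    reason: str


def _resolve_contig(name: str, available: set[str]) -> str | None:
    if name in available:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    return alt if alt in available else None


def build_catalog_from_vcf(
    vcf_path: str | Path,
    fasta_path: str | Path,
    sample_id: str,
) -> tuple[MutationalCatalog, list[SkipRecord]]:
    """Count SBS96 channels for the SNVs of one VCF against a reference FASTA.

    Purine-reference substitutions are reverse-complemented to the pyrimidine
    strand together with their flanks.  Multi-allelic records are split and
    each ALT handled independently.  Non-SNV records, records whose flanks
    fall off a contig or contain N, and records whose REF disagrees with the
    FASTA are skipped and reported in the skip log.
    """
    import pysam
    from pyfaidx import Fasta

    from .channels import canonical_label, channel_index

    counts = np.zeros(96, dtype=np.int64)
    skips: list[SkipRecord] = []
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    contigs = set(fasta.keys())
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            pos = rec.pos  # 1-based
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            for alt in alts:
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    skips.append(SkipRecord(rec.contig, pos, "not_snv"))
                    continue
                contig = _resolve_contig(rec.contig, contigs)
                if contig is None:
                    skips.append(SkipRecord(rec.contig, pos, "contig_not_in_fasta"))
                    continue
                if pos < 2 or pos + 1 > len(fasta[contig]):
                    skips.append(SkipRecord(rec.contig, pos, "flank_outside_contig"))
                    continue
                tri = fasta[contig][pos - 2 : pos + 1]  # 0-based half-open
                if len(tri) != 3 or any(b not in "ACGT" for b in tri):
                    skips.append(SkipRecord(rec.contig, pos, "ambiguous_context"))
                    continue
                if tri[1] != ref:
                    warnings.warn(
                        f"{rec.contig}:{pos} REF {ref} disagrees with FASTA "
                        f"base {tri[1]}; record skipped",
                        stacklevel=2,
                    )
                    skips.append(SkipRecord(rec.contig, pos, "ref_mismatch"))
                    continue
                label = canonical_label(ref, alt, tri[0], tri[2])
                counts[channel_index(label)] += 1
    df = pd.DataFrame({sample_id: counts}, index=pd.Index(CANONICAL_LABELS, name="MutationType"))
    return MutationalCatalog(df), skips
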