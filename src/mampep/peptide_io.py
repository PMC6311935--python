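"""Reading, validating, labeling, splitting and writing peptide datasets.

Peptides come in as CSV tables (columns ``peptide``\\ [, ``ic50``][, ``label``])
or plain FASTA; binder status follows the community convention IC50 < 500 nM.
Generated-peptide collections round-trip through a provenance CSV schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import normalize_sequence

logger = logging.getLogger(__name__)

#: Binder / non-binder IC50 cutoff in nM. The comparison is strict:
#: exactly 500 nM is a non-binder.
BINDER_THRESHOLD_NM: float = 500.0

#: Default admissible peptide lengths for class I binding.
DEFAULT_LENGTH_BOUNDS: tuple[int, int] = (8, 11)


def label_from_ic50(ic50: float, threshold: float = BINDER_THRESHOLD_NM) -> int:
    """Binary binder label from an IC50 in nM: 1 iff ``ic50 < threshold``."""
    ic50 = float(ic50)
    if not ic50 > 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    return int(ic50 < threshold)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide with optional affinity annotation.

    Parameters
    ----------
    sequence
        Peptide over the 20 canonical one-letter codes; normalized to
        uppercase on construction.
    ic50
        Optional half-maximal inhibitory concentration in nM (positive).
    label
        Optional binary binder label (1 = binder). If both ``ic50`` and
        ``label`` are given they must agree under the 500 nM rule.
    allele
        Optional MHC allele tag.
    """

    sequence: str
    ic50: Optional[float] = None
    label: Optional[int] = None
    allele: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.ic50 is not None:
            ic50 = float(self.ic50)
            if not ic50 > 0:
                raise ValueError(f"ic50 must be positive, got {ic50}")
            object.__setattr__(self, "ic50", ic50)
        if self.label is not None:
            if int(self.label) not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {self.label}")
            object.__setattr__(self, "label", int(self.label))
        if self.ic50 is not None and self.label is not None:
            if self.label != label_from_ic50(self.ic50):
                raise ValueError(
                    f"label {self.label} inconsistent with ic50 {self.ic50} nM "
                    f"under the {BINDER_THRESHOLD_NM:g} nM rule"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered, same-allele collection of :class:`PeptideRecord`."""

    records: list[PeptideRecord] = field(default_factory=list)
    allele: str = ""
    split_tag: str = "unsplit"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            raise ValueError("dataset contains unlabeled records")
        return np.asarray(labs, dtype=np.int64)

    def ic50s(self) -> np.ndarray:
        vals = [r.ic50 for r in self.records]
        if any(v is None for v in vals):
            raise ValueError("dataset contains records without ic50")
        return np.asarray(vals, dtype=np.float64)

    def has_ic50(self) -> bool:
        return all(r.ic50 is not None for r in self.records)

    def lengths(self) -> set[int]:
        return {len(r) for r in self.records}

    def subset(self, indices: Sequence[int], split_tag: Optional[str] = None) -> "Dataset":
        return Dataset(
            records=[self.records[i] for i in indices],
            allele=self.allele,
            split_tag=split_tag if split_tag is not None else self.split_tag,
        )


def _read_csv(path: Path, length_bounds, threshold, allele) -> Dataset:
    df = pd.read_csv(path, dtype={"peptide": str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: missing required 'peptide' column")
    known = {"peptide", "ic50", "label", "allele"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)

    records: list[PeptideRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        seq = getattr(row, "peptide")
        if not isinstance(seq, str) or not seq.strip():
            raise ValueError(f"{path}: row {row_no}: empty peptide")
        ic50 = None
        if "ic50" in df.columns:
            raw = getattr(row, "ic50")
            if not (raw is None or (isinstance(raw, float) and np.isnan(raw))):
                try:
                    ic50 = float(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: row {row_no}: non-numeric ic50 {raw!r}"
                    ) from None
                if not ic50 > 0:
                    raise ValueError(f"{path}: row {row_no}: non-positive ic50 {ic50}")
        label = None
        if "label" in df.columns:
            raw = getattr(row, "label")
            if not (raw is None or (isinstance(raw, float) and np.isnan(raw))):
                label = int(raw)
        if label is None and ic50 is not None:
            label = label_from_ic50(ic50, threshold)
        try:
            rec = PeptideRecord(sequence=seq, ic50=ic50, label=label, allele=allele or None)
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from None
        _check_length(rec, length_bounds, f"{path}: row {row_no}")
        records.append(rec)
    return Dataset(records=records, allele=allele)


def _read_fasta(path: Path, length_bounds, allele) -> Dataset:
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        rec = PeptideRecord(sequence=str(sr.seq), allele=allele or None)
        _check_length(rec, length_bounds, f"{path}: record {sr.id}")
        records.append(rec)
    return Dataset(records=records, allele=allele)


def _check_length(rec: PeptideRecord, bounds, where: str) -> None:
    lo, hi = bounds
    if not lo <= len(rec) <= hi:
        raise ValueError(
            f"{where}: peptide length {len(rec)} outside bounds [{lo}, {hi}]"
        )


def _deduplicate(ds: Dataset) -> Dataset:
    seen: set[tuple[str, Optional[int]]] = set()
    by_seq: dict[str, set[Optional[int]]] = {}
    kept: list[PeptideRecord] = []
    n_dup = 0
    for r in ds.records:
        key = (r.sequence, r.label)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        by_seq.setdefault(r.sequence, set()).add(r.label)
        kept.append(r)
    if n_dup:
        logger.info("dropped %d exact (sequence, label) duplicates", n_dup)
    conflicts = [s for s, labs in by_seq.items() if len(labs) > 1]
    if conflicts:
        logger.warning(
            "%d peptides appear with conflicting labels (kept as-is): %s",
            len(conflicts), conflicts[:10],
        )
    return Dataset(records=kept, allele=ds.allele, split_tag=ds.split_tag)


def read_peptide_table(
    path,
    format: Optional[str] = None,
    *,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    threshold: float = BINDER_THRESHOLD_NM,
    allele: str = "",
    deduplicate: bool = True,
) -> Dataset:
    """Read a peptide dataset from CSV or FASTA.

    CSV must carry a header with a ``peptide`` column and may carry ``ic50``
    (nM) and/or ``label``; when only ``ic50`` is present, labels are derived
    with the strict ``< threshold`` rule. Lowercase input is normalized to
    uppercase; row order is preserved. Exact (sequence, label) duplicates are
    dropped; the same sequence appearing with conflicting labels is kept and
    logged, with no attempt to adjudicate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta", ".faa"} else "csv"
    if format == "csv":
        ds = _read_csv(path, length_bounds, threshold, allele)
    elif format == "fasta":
        ds = _read_fasta(path, length_bounds, allele)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _deduplicate(ds) if deduplicate else ds


def split_dataset(dataset: Dataset, test_fraction: float, seed: int) -> tuple[Dataset, Dataset]:
    """Seeded disjoint train/test partition.

    ``|test| = round(test_fraction * n)`` clamped to [1, n-1]; the union of
    the two splits equals the input and input order is preserved within each
    split.
    """
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return (
        dataset.subset(train_idx.tolist(), split_tag="train"),
        dataset.subset(test_idx.tolist(), split_tag="test"),
    )


_GEN_COLUMNS = ["parent", "generated", "mutated_site", "parent_predicted_prob",
                "site_scores", "oracle_ic50"]


def write_generated(path, generated: Iterable) -> None:
    """Write generated peptides with provenance to CSV.

    Columns: parent, generated, mutated_site (1-based), parent_predicted_prob,
    site_scores (semicolon-joined, parent's per-site contributions) and
    oracle_ic50 where available. An empty collection yields a header-only file.
    """
    rows = []
    for g in generated:
        scores = getattr(g, "site_scores", None)
        rows.append({
            "parent": g.parent,
            "generated": g.generated,
            "mutated_site": int(g.mutated_site),
            "parent_predicted_prob": (
                "" if g.parent_prob is None else f"{g.parent_prob:.10g}"
            ),
            "site_scores": (
                "" if scores is None else ";".join(f"{s:.10g}" for s in scores)
            ),
            "oracle_ic50": (
                "" if getattr(g, "oracle_ic50", None) is None else f"{g.oracle_ic50:.10g}"
            ),
        })
    df = pd.DataFrame(rows, columns=_GEN_COLUMNS)
    df.to_csv(path, index=False, lineterminator="\n")


def read_generated(path) -> list:
    """Read a generated-peptide CSV back into :class:`~mampep.generator.GeneratedPeptide`."""
    from .generator import GeneratedPeptide  # deferred: generator imports this module

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype={"parent": str, "generated": str})
    out = []
    for row in df.itertuples(index=False):
        scores = None
        raw = row.site_scores
        if isinstance(raw, str) and raw:
            scores = np.asarray([float(x) for x in raw.split(";")])
        prob = None if pd.isna(row.parent_predicted_prob) else float(row.parent_predicted_prob)
        oracle = None
        if "oracle_ic50" in df.columns and not pd.isna(row.oracle_ic50):
            oracle = float(row.oracle_ic50)
        out.append(GeneratedPeptide(
            parent=row.parent, generated=row.generated,
            mutated_site=int(row.mutated_site), parent_prob=prob,
            site_scores=scores, oracle_ic50=oracle,
        ))
    return out
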