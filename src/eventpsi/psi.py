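"""Per-event inclusion levels (PSI) from transcript abundances.

For an event with transcript sets ``F1`` (reported form) and ``F2``
(alternative form) and per-sample transcript abundances ``TPM_k``:

    PSI = sum_{k in F1} TPM_k / sum_{j in F1 u F2} TPM_j

A PSI value is reported as missing (NA) when the denominator is zero, when
the event's gene fails the expression filter (gene TPM must strictly exceed
``total_filter``), or when none of the event's transcripts appear in the
quantification. Transcripts listed in an event but absent from the
quantification table contribute zero TPM, with a one-time warning each.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from eventpsi.annotation import Annotation
from eventpsi.events import Event, EventCatalog

logger = logging.getLogger(__name__)

NA_CAUSE_ZERO_DENOMINATOR = "zero_denominator"
NA_CAUSE_GENE_FILTER = "gene_expression_filter"
NA_CAUSE_MISSING_TRANSCRIPTS = "all_transcripts_missing"


class QuantificationError(ValueError):
    """A TPM table violates the input contract."""


class PsiValidationError(ValueError):
    """A PSI table contains values outside [0, 1]."""


def read_quantification(paths: Iterable[str | Path] | str | Path) -> pd.DataFrame:
    """Read one or more transcript x sample TPM tables and merge them
    column-wise.

    Each file is tab-separated with a header row of sample names and a
    first column of transcript ids. Transcripts absent from one file get
    NaN in that file's samples. Duplicate sample names across files,
    duplicate transcript rows within a file, and negative TPM values are
    all errors.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[pd.DataFrame] = []
    seen_samples: set[str] = set()
    for path in paths:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise QuantificationError(
                f"{path}: duplicate transcript rows: {dupes[:5]}"
            )
        clash = seen_samples & set(df.columns)
        if clash:
            raise QuantificationError(
                f"{path}: sample name(s) {sorted(clash)} already present in "
                f"an earlier file"
            )
        if (df.to_numpy() < 0).any():
            raise QuantificationError(f"{path}: negative TPM values")
        seen_samples.update(df.columns)
        frames.append(df)
    if not frames:
        raise QuantificationError("no quantification files given")
    merged = pd.concat(frames, axis=1)  # outer join on transcript ids
    merged.index.name = None
    return merged


def _transcript_to_gene(ann_or_catalog: Annotation | EventCatalog) -> dict[str, str]:
    if isinstance(ann_or_catalog, Annotation):
        return ann_or_catalog.transcript_to_gene()
    mapping: dict[str, str] = {}
    for ev in ann_or_catalog.events:
        for tid in ev.all_transcripts:
            mapping[tid] = ev.gene_id
    return mapping


def gene_tpm(
    ann_or_catalog: Annotation | EventCatalog, q: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene total TPM: the sum of the gene's transcript abundances.

    Accepts either a full annotation (every transcript of every gene
    counts) or an event catalog (the transcripts recorded for the gene's
    events count). Transcripts missing from ``q`` contribute zero with a
    warning.
    """
    t2g = _transcript_to_gene(ann_or_catalog)
    by_gene: dict[str, list[str]] = defaultdict(list)
    for tid, gid in t2g.items():
        by_gene[gid].append(tid)
    rows = {}
    for gid, tids in by_gene.items():
        present = [t for t in tids if t in q.index]
        missing = sorted(set(tids) - set(present))
        if missing:
            logger.warning(
                "gene %s: %d transcript(s) absent from quantification "
                "(treated as TPM 0): %s", gid, len(missing), missing[:5],
            )
        if present:
            rows[gid] = q.loc[present].fillna(0.0).sum(axis=0)
        else:
            rows[gid] = pd.Series(0.0, index=q.columns)
    out = pd.DataFrame(rows).T
    return out.loc[sorted(out.index), q.columns]


def _form_sums(
    ev: Event, q: pd.DataFrame, warned: set[str] | None = None
) -> tuple[pd.Series, pd.Series, int]:
    """Per-sample TPM sums of F1 and F1 u F2; also the number of the
    event's transcripts found in the table."""
    f1 = sorted(ev.f1)
    total = sorted(ev.all_transcripts)
    present = [t for t in total if t in q.index]
    for tid in set(total) - set(present):
        if warned is not None and tid not in warned:
            logger.warning(
                "transcript %s not in quantification; treated as TPM 0", tid
            )
            warned.add(tid)
    f1_present = [t for t in f1 if t in q.index]
    f1_sum = (
        q.loc[f1_present].fillna(0.0).sum(axis=0)
        if f1_present
        else pd.Series(0.0, index=q.columns)
    )
    tot_sum = (
        q.loc[present].fillna(0.0).sum(axis=0)
        if present
        else pd.Series(0.0, index=q.columns)
    )
    return f1_sum, tot_sum, len(present)


def compute_psi(
    ev: Event,
    q: pd.DataFrame,
    sample: str,
    total_filter: float | None = None,
    gene_totals: pd.DataFrame | None = None,
) -> float:
    """PSI of one event in one sample; NaN for degenerate cases.

    ``total_filter`` activates the gene-expression filter: the gene's total
    TPM in the sample must be strictly greater than the threshold,
    otherwise NaN is returned. ``gene_totals`` (from :func:`gene_tpm`) is
    only consulted when the filter is active; without it the event's own
    transcript total stands in for the gene total.
    """
    f1_sum, tot_sum, n_present = _form_sums(ev, q)
    if n_present == 0:
        logger.info("event %s: no transcripts quantified -> NA", ev.event_id)
        return float("nan")
    if total_filter is not None:
        if gene_totals is not None and ev.gene_id in gene_totals.index:
            gene_total = float(gene_totals.loc[ev.gene_id, sample])
        else:
            gene_total = float(tot_sum[sample])
        if not gene_total > total_filter:
            return float("nan")
    denom = float(tot_sum[sample])
    if denom == 0.0:
        return float("nan")
    return float(f1_sum[sample]) / denom


def psi_per_event(
    catalog: EventCatalog,
    q: pd.DataFrame,
    total_filter: float | None = None,
    gene_totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """PSI for every event (rows, catalog output order) and sample
    (columns).

    NA causes are counted and logged. Raises
    :class:`QuantificationError` when no transcript of any event is found
    in ``q`` (annotation/quantification mismatch).
    """
    if not catalog.events:
        raise QuantificationError("empty event catalog")
    if q.empty:
        raise QuantificationError("empty quantification matrix")
    if total_filter is not None and gene_totals is None:
        gene_totals = gene_tpm(catalog, q)

    events = catalog.sorted_events()
    any_found = False
    na_causes: Counter[str] = Counter()
    warned: set[str] = set()
    rows = np.full((len(events), q.shape[1]), np.nan)
    for i, ev in enumerate(events):
        f1_sum, tot_sum, n_present = _form_sums(ev, q, warned)
        if n_present == 0:
            na_causes[NA_CAUSE_MISSING_TRANSCRIPTS] += q.shape[1]
            continue
        any_found = True
        f1_vals = f1_sum.to_numpy(dtype=float)
        tot_vals = tot_sum.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(tot_vals > 0, f1_vals / np.maximum(tot_vals, 1e-300), np.nan)
        na_causes[NA_CAUSE_ZERO_DENOMINATOR] += int((tot_vals == 0).sum())
        if total_filter is not None:
            if ev.gene_id in gene_totals.index:
                gt = gene_totals.loc[ev.gene_id, q.columns].to_numpy(dtype=float)
            else:
                gt = tot_vals
            fail = ~(gt > total_filter)
            na_causes[NA_CAUSE_GENE_FILTER] += int((fail & (tot_vals > 0)).sum())
            psi = np.where(fail, np.nan, psi)
        rows[i] = psi
    if not any_found:
        raise QuantificationError(
            "no transcript of any event appears in the quantification; "
            "the ioe and expression files likely come from different "
            "annotations"
        )
    if na_causes:
        logger.info(
            "NA values by cause: %s",
            ", ".join(f"{k}={v}" for k, v in sorted(na_causes.items())),
        )
    out = pd.DataFrame(rows, index=[ev.event_id for ev in events], columns=q.columns)
    out.attrs["na_causes"] = dict(na_causes)
    return out


def write_psi(m: pd.DataFrame, path: str | Path, na_rep: str = "NA") -> None:
    """Write a PSI matrix: tab-separated, sample-name header, event ids in
    the first column, missing values as ``NA`` (or ``na_rep``)."""
    path = Path(path)
    m.to_csv(path, sep="\t", na_rep=na_rep, index_label="event_id")


def read_psi(path: str | Path, na_values: tuple[str, ...] = ("NA", "nan")) -> pd.DataFrame:
    """Read a PSI matrix written by :func:`write_psi`, validating that all
    values lie in [0, 1]."""
    m = pd.read_csv(path, sep="\t", index_col=0, na_values=list(na_values))
    vals = m.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.nansum(bad) > 0:
        i, j = np.argwhere(bad)[0]
        raise PsiValidationError(
            f"{path}: PSI value {vals[i, j]} out of [0, 1] "
            f"(event {m.index[i]}, sample {m.columns[j]})"
        )
    m.index = m.index.astype(str)
    m.columns = m.columns.astype(str)
    m.index.name = None
    return m
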