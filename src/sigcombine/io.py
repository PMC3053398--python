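"""Readers and writers for the external formats the pipeline touches.

Expression matrices and clinical tables are UTF-8 tab-separated text; gene
sets use the standard GMT layout; platform annotation is a TSV with columns
``probe_id, unigene, symbol, aliases`` (aliases pipe-separated); run
configuration is YAML mirroring :class:`~sigcombine.containers.RunConfig`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RunConfig,
    SurvivalData,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: cell tokens treated as missing in all tabular inputs (SMD-style exports)
NA_TOKENS = ("", "NA", "NaN", "null")


class ParseError(ValueError):
    """Raised on malformed input files, with row/column context."""


def _parse_cell(token: str, path, row_label: str, col_label: str) -> float:
    token = token.strip()
    if token in NA_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric cell {token!r} at gene {row_label!r}, "
            f"sample {col_label!r}"
        ) from None


def read_expression(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV (first row sample ids)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if len(header) < 2:
            raise ParseError(f"{path}: malformed header (needs >= 2 columns)")
        sample_ids = [h.strip() for h in header[1:]]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            gid = fields[0].strip()
            if gid in seen:
                raise ParseError(f"{path}: duplicated gene id {gid!r}")
            seen.add(gid)
            cells = fields[1:]
            if len(cells) != len(sample_ids):
                raise ParseError(
                    f"{path}: gene {gid!r} has {len(cells)} cells, "
                    f"expected {len(sample_ids)}"
                )
            rows.append(
                [_parse_cell(c, path, gid, s) for c, s in zip(cells, sample_ids)]
            )
            gene_ids.append(gid)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        missing_mask=np.isnan(values),
    )
    logger.info("read_expression: %s -> %d genes x %d samples (%d missing cells)",
                path, matrix.n_genes, matrix.n_samples, int(matrix.missing_mask.sum()))
    return matrix


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    path = Path(path)
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter, na_rep="NA", encoding="utf-8")


def read_gmt(path, namespace: str = "symbol") -> GeneSetCollection:
    """Read gene sets from a GMT file: name, description, gene tokens.

    All identifiers in a file share one ``namespace`` (per-file default).
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0].strip(), fields[1].strip()
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            names.add(name)
            genes = [(g.strip(), namespace) for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, genes=genes, description=desc))
    logger.info("read_gmt: %s -> %d sets, sizes %s",
                path, len(sets), [s.size for s in sets])
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            tokens = [ident for ident, _ in s.genes]
            fh.write("\t".join([s.name, s.description or "na", *tokens]) + "\n")


def read_clinical(
    path,
    time_column: str,
    event_column: str,
    sample_column: str | None = None,
    time_unit_factor: float = 1.0,
    delimiter: str = "\t",
) -> SurvivalData:
    """Read a clinical TSV into survival data.

    ``time_unit_factor`` converts the stored time unit to months (e.g. pass
    ``12.0`` for years).  Every column other than sample id, time and event
    is preserved as a covariate; missing covariate levels are allowed.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, na_values=list(NA_TOKENS),
                        keep_default_na=False, encoding="utf-8")
    if sample_column is None:
        sample_column = frame.columns[0]
    for col in (sample_column, time_column, event_column):
        if col not in frame.columns:
            raise ParseError(f"{path}: required column {col!r} not found")
    sample_ids = [str(s) for s in frame[sample_column]]
    time = pd.to_numeric(frame[time_column], errors="coerce").to_numpy() * time_unit_factor
    if np.any(np.isnan(time)):
        bad = [sample_ids[i] for i in np.flatnonzero(np.isnan(time))]
        raise ValidationError(f"{path}: non-numeric follow-up time for {bad}")
    event_raw = frame[event_column]
    event = pd.to_numeric(event_raw, errors="coerce").to_numpy()
    if np.any(np.isnan(event)) or not np.all(np.isin(event[~np.isnan(event)], [0, 1])):
        raise ValidationError(
            f"{path}: event column {event_column!r} must coerce to {{0,1}}"
        )
    covariates = frame.drop(columns=[sample_column, time_column, event_column])
    covariates.index = pd.Index(sample_ids)
    surv = SurvivalData(sample_ids=sample_ids, time=time, event=event,
                        covariates=covariates)
    logger.info("read_clinical: %s -> %d samples, %d events, covariates %s",
                path, surv.n, surv.n_events, list(covariates.columns))
    return surv


def write_clinical(surv: SurvivalData, path, delimiter: str = "\t") -> None:
    frame = pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    )
    frame = pd.concat([frame.set_index("sample_id"), surv.covariates], axis=1)
    frame.index.name = "sample_id"
    frame.to_csv(Path(path), sep=delimiter, na_rep="NA", encoding="utf-8")


def read_annotation(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a platform annotation TSV (probe_id, unigene, symbol, aliases)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, na_values=list(NA_TOKENS),
                        keep_default_na=False, dtype=str, encoding="utf-8")
    required = {"probe_id", "unigene", "symbol", "aliases"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: annotation missing columns {sorted(missing)}")
    if frame["probe_id"].duplicated().any():
        dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"{path}: duplicate probe ids {dups}")
    return frame


def read_config(path) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(vars(config).copy(), fh, sort_keys=True)
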