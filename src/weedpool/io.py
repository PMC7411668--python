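"""Delimited-text I/O, the deposited-dataset adapter, and report assembly.

All tabular I/O is header-named, never position-based; the delimiter is
auto-detected between comma and tab and can be overridden. Writes log row
counts; reads fail with the missing column names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from ._util import logger
from .contingency import HabitatCountTable
from .pool import SpeciesPool, TaxonRecord, normalize_name

_ATTR_COLS = ("family", "life_form", "origin", "red_list")


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    if delimiter is None:
        header = path.open(encoding="utf-8").readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_occurrences(path: str | Path, delimiter: str | None = None) -> list[tuple[str, str]]:
    """Read (plot_id, species_id) occurrence records."""
    df = _read_table(path, delimiter)
    _require(df, ("plot_id", "species_id"), path)
    records = list(zip(df["plot_id"], df["species_id"]))
    logger.info("read %d occurrence records from %s", len(records), path)
    return records


def read_taxa(path: str | Path, delimiter: str | None = None) -> list[dict[str, str]]:
    """Read one source's taxon rows (required column: name)."""
    df = _read_table(path, delimiter)
    _require(df, ("name",), path)
    rows = df.to_dict(orient="records")
    logger.info("read %d taxon rows from %s", len(rows), path)
    return rows


def write_pool(pool: SpeciesPool, path: str | Path, delimiter: str = "\t") -> None:
    """Write the pool as one row per taxon with 0/1 membership columns."""
    rows = []
    for t in pool.taxa:
        row = {"taxon_id": t.taxon_id, "name": t.name}
        row.update({a: getattr(t, a) for a in _ATTR_COLS})
        row.update({s: int(s in t.memberships) for s in pool.sources})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    logger.info("wrote %d taxa to %s", len(rows), path)


def read_pool(path: str | Path, sources: Sequence[str],
              delimiter: str | None = None) -> SpeciesPool:
    """Read a pool table written by :func:`write_pool`."""
    df = _read_table(path, delimiter)
    _require(df, ("name", *sources), path)
    taxa = []
    for rec in df.to_dict(orient="records"):
        attrs = {a: rec.get(a, "unknown") or "unknown" for a in _ATTR_COLS}
        taxa.append(TaxonRecord(
            taxon_id=rec.get("taxon_id") or rec["name"],
            name=rec["name"],
            memberships={s for s in sources if str(rec[s]) in ("1", "True", "true")},
            **attrs,
        ))
    return SpeciesPool(taxa=taxa, sources=list(sources))


def ingest_deposited_dataset(
    path: str | Path,
    column_map: Mapping[str, str],
    delimiter: str | None = None,
) -> SpeciesPool:
    """Adapter for an externally deposited pool file with arbitrary headers.

    ``column_map`` maps our field names to the file's column names: a
    ``name`` entry is required; entries whose key matches a taxon attribute
    map attribute columns; every other entry declares a source, whose
    column is read as a truthy membership flag (1/0, true/false, x/blank).
    """
    if not column_map:
        raise ValueError("column_map is empty; at least 'name' must be mapped")
    if "name" not in column_map:
        raise ValueError("column_map must map 'name'")
    df = _read_table(path, delimiter)
    _require(df, list(column_map.values()), path)
    attr_keys = [k for k in column_map if k in _ATTR_COLS]
    source_keys = [k for k in column_map if k not in _ATTR_COLS and k != "name"]
    taxa = []
    seen: set[str] = set()
    for rec in df.to_dict(orient="records"):
        name = normalize_name(rec[column_map["name"]])
        if name in seen:
            logger.warning("deposited dataset: duplicate taxon %r collapsed", name)
            continue
        seen.add(name)
        attrs = {k: rec[column_map[k]] or "unknown" for k in attr_keys}
        member = {
            s for s in source_keys
            if str(rec[column_map[s]]).strip().lower() in ("1", "true", "x", "yes")
        }
        taxa.append(TaxonRecord(taxon_id=name, name=name, memberships=member,
                                **attrs))
    logger.info("ingested %d taxa from deposited dataset %s", len(taxa), path)
    return SpeciesPool(taxa=taxa, sources=source_keys)


def write_venn(counts: Mapping[tuple[str, ...], int], path: str | Path,
               delimiter: str = "\t") -> None:
    rows = [{"region": "&".join(k), "count": v} for k, v in sorted(counts.items())]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    logger.info("wrote %d venn regions to %s", len(rows), path)


def write_report(
    results: Mapping[str, object], out_dir: str | Path,
    params: Mapping[str, object] | None = None,
) -> Path:
    """Assemble a run report: manifest plus any tables in ``results``.

    ``results`` values that are HabitatCountTable instances are rendered in
    the observed(expected) convention; DataFrames are written as TSV;
    everything else lands in the JSON manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "tool": "weedpool",
        "version": __version__,
        "parameters": dict(params or {}),
        "tables": {},
    }
    for key, val in results.items():
        if isinstance(val, HabitatCountTable):
            df = pd.DataFrame({
                "habitat": val.habitats,
                "reference": val.reference,
                "observed_expected": val.formatted(),
            })
            dest = out / f"{key}.tsv"
            df.to_csv(dest, sep="\t", index=False)
            manifest["tables"][key] = {
                "rows": len(df), "chi2": val.test.chi2, "df": val.test.df,
                "p": val.test.p,
            }
        elif isinstance(val, pd.DataFrame):
            dest = out / f"{key}.tsv"
            val.to_csv(dest, sep="\t", index=False)
            manifest["tables"][key] = {"rows": len(val)}
        else:
            manifest[key] = val
    dest = out / "manifest.json"
    dest.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    logger.info("report written to %s", out)
    return dest
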