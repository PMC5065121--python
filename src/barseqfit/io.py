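"""Readers and writers for the pipeline's tabular formats.

All tables are TSV with a mandatory header row, preceded by ``#``-prefixed
comment lines recording the tool version, seed, and parameters, so that
every output is self-describing and byte-reproducible for a fixed
configuration.  Counts tables encode their (condition, replicate,
timepoint) sample columns as ``<condition>_r<rep>_g<gen>``.
"""

from __future__ import annotations

import re
import warnings
from collections.abc import Mapping, Sequence

import pandas as pd

from . import __version__
from .pool import StrainSpec

__all__ = [
    "read_catalog",
    "write_catalog",
    "validate_catalog",
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "CatalogError",
]

_SAMPLE_RE = re.compile(r"^(?P<cond>.+)_r(?P<rep>\d+)_g(?P<gen>\d+)$")


class CatalogError(ValueError):
    pass


def _header_lines(meta: Mapping | None) -> str:
    lines = [f"# barseqfit {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def write_table(
    frame: pd.DataFrame,
    path,
    meta: Mapping | None = None,
    index: bool = True,
    float_format: str | None = "%.6g",
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=index, float_format=float_format)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col,
        float_precision="round_trip",
    )


def write_catalog(catalog: Sequence[StrainSpec], path, meta: Mapping | None = None) -> None:
    frame = pd.DataFrame(
        [
            (st.strain_id, st.barcode, st.gene, st.collection, st.true_fitness)
            for st in catalog
        ],
        columns=["strain_id", "barcode", "gene", "collection", "true_fitness"],
    )
    # full float precision so catalogs round-trip losslessly
    write_table(frame, path, meta, index=False, float_format="%.17g")


def validate_catalog(frame: pd.DataFrame, source: str = "catalog") -> list[StrainSpec]:
    """Validate a parsed catalog table into StrainSpec records.

    Malformed rows (wrong barcode length or alphabet, bad fitness) are
    rejected with their line positions.  Barcodes appearing under more than
    one gene are legal but flagged with a warning — the counting stage
    discards their reads as ambiguous.
    """
    required = ["strain_id", "barcode", "gene", "collection", "true_fitness"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CatalogError(f"{source}: missing columns {missing}")
    strains, errors = [], []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            strains.append(
                StrainSpec(
                    strain_id=str(row.strain_id),
                    barcode=str(row.barcode),
                    gene=str(row.gene),
                    collection=str(row.collection),
                    true_fitness=float(row.true_fitness),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {pos}: {exc}")
    if errors:
        raise CatalogError(f"{source}: {len(errors)} bad rows\n" + "\n".join(errors))
    seen: dict[str, list[str]] = {}
    for st in strains:
        seen.setdefault(st.barcode, []).append(st.gene)
    dupes = {bc: genes for bc, genes in seen.items() if len(set(genes)) > 1 or len(genes) > 1}
    if dupes:
        warnings.warn(
            f"{source}: {len(dupes)} barcodes shared by multiple entries; "
            "their reads will be counted as ambiguous"
        )
    return strains


def read_catalog(path) -> list[StrainSpec]:
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", float_precision="round_trip"
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise CatalogError(f"cannot read catalog {path}: {exc}") from exc
    return validate_catalog(frame, source=str(path))


def write_counts(counts: pd.DataFrame, path, meta: Mapping | None = None) -> None:
    flat = counts.copy()
    if isinstance(flat.columns, pd.MultiIndex):
        flat.columns = [f"{c}_r{r}_g{t}" for c, r, t in flat.columns]
    write_table(flat, path, meta)


def read_counts(path) -> pd.DataFrame:
    flat = read_table(path)
    keys = []
    for col in flat.columns:
        m = _SAMPLE_RE.match(col)
        if not m:
            raise ValueError(
                f"column {col!r} does not look like <condition>_r<rep>_g<gen>"
            )
        keys.append((m["cond"], int(m["rep"]), int(m["gen"])))
    flat.columns = pd.MultiIndex.from_tuples(
        keys, names=["condition", "replicate", "timepoint"]
    )
    return flat
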