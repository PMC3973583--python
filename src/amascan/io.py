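"""TSV readers and writers for every pipeline artifact.

All files are plain TSV.  Outputs begin with ``#`` comment lines recording
the tool version, the generating parameters and the seed, so any table can
be traced back to the run that produced it; readers skip those lines.
Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, GeneCatalog

__all__ = [
    "header_lines",
    "read_expression",
    "write_expression",
    "read_groups",
    "write_groups",
    "read_catalog",
    "write_catalog",
    "read_annotations",
    "write_annotations",
    "read_table",
    "write_table",
]


def header_lines(params: dict | None = None, seed: int | None = None) -> str:
    """Provenance comment block prepended to every output file."""
    lines = [f"# amascan v{__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    for k, v in (params or {}).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def _open_text(path) -> list[str]:
    text = Path(path).read_text()
    return text.splitlines()


def read_expression(path, groups_path=None) -> ExpressionMatrix:
    """Parse a genes-x-samples intensity TSV (+ optional sample->group map).

    The first non-comment line is the header: ``gene`` followed by sample
    ids.  Errors name the offending 1-based line number.
    """
    lines = _open_text(path)
    header = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if header is None:
            header = fields
        else:
            rows.append((lineno, fields))
    if header is None or not rows:
        raise ValueError(f"{path}: no genes")

    samples = header[1:]
    n_cols = len(header)
    genes, data, seen = [], [], set()
    for lineno, fields in rows:
        if len(fields) != n_cols:
            raise ValueError(f"{path}:{lineno}: expected {n_cols} columns, got {len(fields)}")
        gene = fields[0]
        if gene in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            values = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric intensity ({exc})") from None
        genes.append(gene)
        data.append(values)

    values = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    if groups_path is not None:
        groups = read_groups(groups_path)
    else:
        # fall back to "everything before the last _rN" as the group name
        groups = {s: s.rsplit("_", 1)[0] for s in samples}
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines(seed=seed))
        expr.values.to_csv(fh, sep="\t", index_label="gene")


def read_groups(path) -> dict[str, str]:
    """Two-column (sample, group) TSV -> mapping."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "group"}.issubset(tab.columns):
        raise ValueError(f"{path}: needs columns sample, group")
    return dict(zip(tab["sample"], tab["group"]))


def write_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines())
        pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
            fh, sep="\t", index=False
        )


def read_catalog(path, terms_path=None, domains_path=None) -> GeneCatalog:
    """BED-like catalog TSV (gene, arm, start, end) with optional annotations.

    Arm lengths are taken from ``# arm_length <arm> <bp>`` header comments
    when present, otherwise inferred as the largest end coordinate per arm.
    """
    arm_lengths: dict[str, int] = {}
    for line in _open_text(path):
        if line.startswith("# arm_length"):
            _, _, arm, length = line.split()
            arm_lengths[arm] = int(length)
        elif not line.startswith("#"):
            break
    genes = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"gene": str, "arm": str, "start": int, "end": int},
    )
    if not {"gene", "arm", "start", "end"}.issubset(genes.columns):
        raise ValueError(f"{path}: needs columns gene, arm, start, end")
    if not arm_lengths:
        arm_lengths = genes.groupby("arm")["end"].max().astype(int).to_dict()
    terms = read_annotations(terms_path, "term") if terms_path else None
    domains = read_annotations(domains_path, "domain") if domains_path else None
    kwargs = {}
    if terms is not None:
        kwargs["terms"] = terms
    if domains is not None:
        kwargs["domains"] = domains
    return GeneCatalog(genes=genes, arm_lengths=arm_lengths, **kwargs)


def write_catalog(catalog: GeneCatalog, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines(seed=seed))
        for arm, length in catalog.arm_lengths.items():
            fh.write(f"# arm_length {arm} {length}\n")
        catalog.genes.to_csv(fh, sep="\t", index=False)


def read_annotations(path, kind: str) -> pd.DataFrame:
    """Two-column (gene, <kind>) TSV; repeated rows carry multiplicity."""
    tab = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"gene", kind}.issubset(tab.columns):
        raise ValueError(f"{path}: needs columns gene, {kind}")
    return tab[["gene", kind]]


def write_annotations(tab: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(header_lines(seed=seed))
        tab.to_csv(fh, sep="\t", index=False)


def read_table(path, index_col=None) -> pd.DataFrame:
    """Generic TSV table reader skipping ``#`` comment headers."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_table(
    tab: pd.DataFrame, path, params: dict | None = None, seed: int | None = None, index: bool = False
) -> None:
    """Generic TSV table writer with a provenance header."""
    with open(path, "w") as fh:
        fh.write(header_lines(params=params, seed=seed))
        tab.to_csv(fh, sep="\t", index=index)
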