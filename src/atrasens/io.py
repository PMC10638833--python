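"""Readers and writers for the pipeline's tabular formats.

All files are plain-text, UTF-8, tab-separated (with GCT 1.2 accepted for
expression and GMT for gene sets).  Readers validate the invariants the
downstream stages rely on; writers produce files the readers round-trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .consensus import DE_COLUMNS, _validate_de
from .dose_response import GROWTH_COLUMNS, _validate_growth
from .signature import SensitivitySignature
from .subtype import SubtypeTemplate


def read_growth_table(path: str | Path) -> pd.DataFrame:
    """Long-format growth table: cell_line, concentration_uM, day, replicate, viability."""
    tab = pd.read_csv(path, sep="\t")
    return _validate_growth(tab)


def write_growth_table(table: pd.DataFrame, path: str | Path) -> None:
    table[GROWTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample log2-CPM matrix from TSV (first column = gene) or GCT 1.2."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        expr = pd.read_csv(path, sep="\t", skiprows=2)
        expr = expr.drop(columns=[c for c in ("Description", "description") if c in expr.columns])
        expr = expr.set_index(expr.columns[0])
    else:
        expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    if expr.index.duplicated().any():
        raise ValueError(f"duplicate gene ids in {path}")
    if expr.columns.duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    if not np.all(np.isfinite(expr.to_numpy(dtype=float))):
        raise ValueError(f"non-finite expression values in {path}")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.rename_axis("gene").to_csv(path, sep="\t")


def read_interaction_graph(path: str | Path, min_confidence: float | None = None) -> nx.Graph:
    """Undirected edge list ``geneA<TAB>geneB[<TAB>confidence]``.

    Self-loops are dropped with a warning, duplicate edges collapse, and
    edges below ``min_confidence`` (when given) are skipped.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or (lineno == 1 and line.lower().startswith("genea")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            a, b = parts[0], parts[1]
            conf = float(parts[2]) if len(parts) > 2 else None
            if a == b:
                n_self += 1
                continue
            if min_confidence is not None and conf is not None and conf < min_confidence:
                continue
            if conf is None:
                g.add_edge(a, b)
            else:
                g.add_edge(a, b, confidence=conf)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s) while reading {path}", stacklevel=2)
    return g


def write_interaction_graph(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\n")
        for a, b in sorted(map(sorted, graph.edges())):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one gene set per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "atrasens") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_signature(sig: SensitivitySignature, gmt_path: str | Path,
                    detail_path: str | Path | None = None, name: str = "ATRA_SENSITIVITY") -> None:
    """Signature as a two-record GMT (``*_DIRECT``/``*_INVERSE``) + detail TSV."""
    sets = {}
    if sig.direct:
        sets[f"{name}_DIRECT"] = list(sig.direct)
    if sig.inverse:
        sets[f"{name}_INVERSE"] = list(sig.inverse)
    write_gmt(sets, gmt_path)
    if detail_path is not None:
        sig.stats.to_csv(detail_path, sep="\t", index=False)


def read_signature(gmt_path: str | Path) -> SensitivitySignature:
    sets = read_gmt(gmt_path)
    direct = next((v for k, v in sets.items() if k.endswith("_DIRECT")), [])
    inverse = next((v for k, v in sets.items() if k.endswith("_INVERSE")), [])
    if not direct and not inverse:
        raise ValueError(f"no *_DIRECT or *_INVERSE record in {gmt_path}")
    stats = pd.DataFrame({
        "gene": list(direct) + list(inverse),
        "direction": ["direct"] * len(direct) + ["inverse"] * len(inverse),
    })
    return SensitivitySignature(direct=list(direct), inverse=list(inverse), stats=stats)


def read_template(path: str | Path) -> SubtypeTemplate:
    """Subtype template from two-column TSV ``gene<TAB>class`` or GMT (set = class)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if len(first) >= 3:  # GMT record
        sets = read_gmt(path)
        entries: dict[str, str] = {}
        for cls, genes in sets.items():
            for g in genes:
                if g in entries:
                    raise ValueError(f"gene {g!r} assigned to multiple classes")
                entries[g] = cls
        return SubtypeTemplate(entries)
    tab = pd.read_csv(path, sep="\t")
    if list(tab.columns[:2]) != ["gene", "class"]:
        tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "class"])
    if tab["gene"].duplicated().any():
        raise ValueError(f"duplicate genes in template {path}")
    return SubtypeTemplate(dict(zip(tab["gene"].astype(str), tab["class"].astype(str))))


def write_template(template: SubtypeTemplate, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tclass\n")
        for gene, cls in template.entries.items():
            fh.write(f"{gene}\t{cls}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    tab["gene"] = tab["gene"].astype(str)
    return _validate_de(tab)


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    table[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> dict[str, list[Path]]:
    """Group manifest YAML: ``groups: {name: [de_table.tsv, ...]}``.

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "groups" not in doc or not isinstance(doc["groups"], dict):
        raise ValueError(f"manifest {path} must contain a 'groups' mapping")
    out = {}
    for group, files in doc["groups"].items():
        if not isinstance(files, list) or not files:
            raise ValueError(f"group {group!r} must list >=1 DE table")
        out[str(group)] = [(path.parent / f) if not Path(f).is_absolute() else Path(f)
                           for f in files]
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """ATRA-score table with 2-decimal display scores plus full precision."""
    out = table.copy()
    out["atra_score_exact"] = out["atra_score"]
    out["atra_score"] = out["atra_score"].round(2)
    cols = ["cell_line", "auc", "atra_score", "call", "atra_score_exact"]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", index=False)


def read_score_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if "atra_score_exact" in tab.columns:
        tab["atra_score"] = tab["atra_score_exact"]
        tab = tab.drop(columns=["atra_score_exact"])
    return tab


def write_enrichment_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_subtype_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
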