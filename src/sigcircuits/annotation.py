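"""Annotation of circuits with effector cell functions and cancer hallmarks.

A circuit's function is the function its effector protein performs; effector
genes are additionally mapped to the canonical acquired capabilities of tumor
cells ("cancer hallmarks").  Both mappings are consumed as static TSV tables
— a curated default set covering common signaling effectors ships with the
package — so no network lookup is involved.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import FormatError
from .pathway import Circuit

UNANNOTATED = "unannotated"

#: The canonical ten acquired capabilities of tumors.
HALLMARK_VOCABULARY = (
    "Sustaining proliferative signaling",
    "Evading growth suppressors",
    "Resisting cell death",
    "Enabling replicative immortality",
    "Inducing angiogenesis",
    "Activating invasion and metastasis",
    "Genome instability and mutation",
    "Tumor-promoting inflammation",
    "Deregulating cellular energetics",
    "Avoiding immune destruction",
)


def _load_mapping(table, key_col: str, value_col: str) -> dict[str, list[str]]:
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    for col in (key_col, value_col):
        if col not in table.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    out: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        terms = [t.strip() for t in str(row[value_col]).split(";") if t.strip()]
        out.setdefault(str(row[key_col]).strip(), []).extend(terms)
    return out


def load_function_table(table) -> dict[str, list[str]]:
    """effector gene -> list of function terms."""
    return _load_mapping(table, "effector_gene", "functions")


def load_hallmark_table(table, vocabulary: Sequence[str] = HALLMARK_VOCABULARY,
                        ) -> dict[str, list[str]]:
    """effector gene -> list of hallmark names, validated against the vocabulary."""
    mapping = _load_mapping(table, "effector_gene", "hallmarks")
    vocab = set(vocabulary)
    for gene, marks in mapping.items():
        bad = [m for m in marks if m not in vocab]
        if bad:
            raise FormatError(
                f"hallmarks {bad} for {gene!r} not in the declared vocabulary")
    return mapping


def default_function_table() -> dict[str, list[str]]:
    with resources.files("sigcircuits.data").joinpath(
            "effector_functions.tsv").open() as fh:
        return load_function_table(pd.read_csv(fh, sep="\t", dtype=str))


def default_hallmark_table() -> dict[str, list[str]]:
    with resources.files("sigcircuits.data").joinpath(
            "effector_hallmarks.tsv").open() as fh:
        return load_hallmark_table(pd.read_csv(fh, sep="\t", dtype=str))


def _effector_genes(circuit: Circuit,
                    gene_lookup: Mapping[str, tuple[str, ...]]) -> tuple[str, ...]:
    return gene_lookup.get(circuit.effector, ())


def annotate_circuits(
    circuits: Sequence[Circuit],
    functions: Mapping[str, list[str]],
    hallmarks: Mapping[str, list[str]],
    effector_genes: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Attach function and hallmark lists to every circuit.

    Lookup is by the genes of the effector node (``effector_genes`` maps
    effector node id -> gene tuple; when omitted the effector node id itself
    is used as the gene symbol).  Effectors absent from the function table
    get the explicit term ``"unannotated"``; absent hallmarks stay empty.
    """
    rows = []
    for c in circuits:
        genes = (effector_genes or {}).get(c.effector, (c.effector,))
        funcs: list[str] = []
        marks: list[str] = []
        for g in genes:
            funcs.extend(functions.get(g, []))
            marks.extend(hallmarks.get(g, []))
        rows.append({
            "circuit_id": c.circuit_id,
            "pathway_id": c.pathway_id,
            "effector": c.effector,
            "effector_genes": ";".join(genes),
            "functions": ";".join(dict.fromkeys(funcs)) or UNANNOTATED,
            "hallmarks": ";".join(dict.fromkeys(marks)),
        })
    return pd.DataFrame(rows, columns=["circuit_id", "pathway_id", "effector",
                                       "effector_genes", "functions",
                                       "hallmarks"])


def hallmark_summary(
    results: pd.DataFrame,
    annotated: pd.DataFrame,
    vocabulary: Sequence[str] = HALLMARK_VOCABULARY,
) -> pd.DataFrame:
    """Count significant circuits per hallmark.

    A circuit mapped to k hallmarks contributes to all k counts; the
    multi-counting rule is recorded in ``DataFrame.attrs['counting']``.
    """
    sig = set(results.loc[results["significant"].astype(bool), "circuit_id"])
    counts = {h: 0 for h in vocabulary}
    for _, row in annotated.iterrows():
        if row["circuit_id"] not in sig:
            continue
        for mark in str(row["hallmarks"]).split(";"):
            mark = mark.strip()
            if mark:
                counts[mark] = counts.get(mark, 0) + 1
    out = pd.DataFrame({"hallmark": list(counts), "n_significant_circuits":
                        list(counts.values())})
    out.attrs["counting"] = "multi-count: a circuit with k hallmarks adds 1 to each"
    return out


def pervasiveness(
    results_per_condition: Mapping[str, pd.DataFrame],
    min_conditions: int = 4,
) -> pd.DataFrame:
    """Circuits significant in at least ``min_conditions`` conditions.

    Rows carry the conditions where the circuit was significant, sorted by
    count descending then circuit_id.
    """
    hits: dict[str, list[str]] = {}
    for cond in sorted(results_per_condition):
        table = results_per_condition[cond]
        for cid in table.loc[table["significant"].astype(bool), "circuit_id"]:
            hits.setdefault(cid, []).append(cond)
    rows = [{"circuit_id": cid, "n_conditions": len(conds),
             "conditions": ";".join(conds)}
            for cid, conds in hits.items() if len(conds) >= min_conditions]
    df = pd.DataFrame(rows, columns=["circuit_id", "n_conditions", "conditions"])
    return df.sort_values(["n_conditions", "circuit_id"],
                          ascending=[False, True]).reset_index(drop=True)
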