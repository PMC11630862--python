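"""Fermentation end-product pathway completeness from enzyme inventories.

Given a genome × enzyme presence/absence matrix (the shape produced by
screening MAGs for fermentation enzymes), each end product (acetate,
ethanol, lactate, succinate, formate, butyrate) is called complete or
incomplete by evaluating a boolean AND/OR rule over the presence set.
Rules live in a versioned YAML config, not in code; the enzyme vocabulary
is the controlled set of inventory row labels, and mapping from external
annotation identifiers (EC/KO numbers) to it is a user concern.

Two ethanol rules ship: the default (alcohol dehydrogenase alone), which
reproduces the published completeness calls for the three enrichment MAGs,
and a biochemically strict alternative additionally requiring acetaldehyde
dehydrogenase.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
import yaml

__all__ = ["EnzymeInventory", "PathwayRuleSet", "UnknownEnzymeError",
           "normalise_label", "load_inventory", "load_rules",
           "packaged_inventory_path", "evaluate_products", "completeness_report"]

Expr = Union[str, Mapping[str, Sequence["Expr"]]]


class UnknownEnzymeError(ValueError):
    """An enzyme label is not in the controlled vocabulary."""


_HYPHENS = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


def normalise_label(label: str) -> str:
    """Canonical display form: NFKC, ASCII hyphens, collapsed whitespace, lowercase."""
    s = unicodedata.normalize("NFKC", str(label)).translate(_HYPHENS)
    return re.sub(r"\s+", " ", s).strip().lower()


def _match_key(label: str) -> str:
    """Matching key: canonical form with spaces/hyphens removed, so
    'phosphate acetyltransferase' and 'phosphate acetyl transferase' agree."""
    return re.sub(r"[\s\-]", "", normalise_label(label))


#: Controlled enzyme vocabulary (canonical inventory row labels).
VOCABULARY = [
    "phosphate acetyl transferase",
    "acetate kinase",
    "acetaldehyde dehydrogenase",
    "alcohol dehydrogenase",
    "lactate dehydrogenase",
    "d-lactate dehydrogenase",
    "malate dehydrogenase (quinone)",
    "malate dehydrogenase (oxaloacetate-decarboxylating)",
    "malate dehydrogenase (oxaloacetate-decarboxylating) (nadp+)",
    "fumarate hydratase",
    "formate acetyltransferase (pyruvate-formate lyase)",
    "pyruvate-formate lyase activating enzyme",
    "pyruvate-ferredoxin oxidoreductase",
    "acetyl-coa c-acetyltransferase",
    "3-hydroxybutyryl-coa dehydrogenase",
    "4-hydroxybutyryl-coa dehydratase",
    "butyryl-coa dehydrogenase",
    "phosphotransbutyrylase",
    "butyrate kinase",
]

_VOCAB_BY_KEY = {_match_key(v): v for v in VOCABULARY}


def canonical_enzyme(label: str) -> str:
    """Resolve a label to the vocabulary, or raise with nearest matches."""
    key = _match_key(label)
    try:
        return _VOCAB_BY_KEY[key]
    except KeyError:
        near = difflib.get_close_matches(normalise_label(label), VOCABULARY, n=3)
        raise UnknownEnzymeError(
            f"unknown enzyme label {label!r}; nearest vocabulary matches: {near}"
        )


@dataclass
class EnzymeInventory:
    """One genome's set of detected fermentation enzymes."""

    genome_id: str
    present_enzymes: frozenset[str]

    @classmethod
    def from_labels(cls, genome_id: str, labels: Iterable[str]) -> "EnzymeInventory":
        return cls(genome_id, frozenset(canonical_enzyme(x) for x in labels))

    def has(self, enzyme: str) -> bool:
        return canonical_enzyme(enzyme) in self.present_enzymes


@dataclass
class PathwayRuleSet:
    """Product → boolean AND/OR expression tree over enzyme names."""

    version: str
    products: dict[str, Expr]

    def __post_init__(self) -> None:
        for product, expr in self.products.items():
            _validate_expr(expr, product)


def _validate_expr(expr: Expr, product: str) -> None:
    if isinstance(expr, str):
        canonical_enzyme(expr)
        return
    if isinstance(expr, Mapping) and len(expr) == 1:
        (op, operands), = expr.items()
        if op in ("all", "any") and isinstance(operands, Sequence) and operands:
            for sub in operands:
                _validate_expr(sub, product)
            return
    raise ValueError(f"malformed rule expression for {product!r}: {expr!r}")


def _eval_expr(expr: Expr, present: frozenset[str]) -> bool:
    if isinstance(expr, str):
        return canonical_enzyme(expr) in present
    (op, operands), = expr.items()
    fn = all if op == "all" else any
    return fn(_eval_expr(sub, present) for sub in operands)


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

_PRESENT_TOKENS = {"+", "1", "true", "yes", "present"}
_ABSENT_TOKENS = {"-", "0", "false", "no", "absent", ""}


def load_inventory(path: str | Path, delimiter: str = "\t") -> list[EnzymeInventory]:
    """Read an enzyme × genome presence matrix (+/− or 1/0 cells).

    The first column holds enzyme labels; remaining columns are genome ids.
    Returns one inventory per genome column.
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    if df.shape[1] < 1:
        return []
    enzyme_col = df.columns[0]
    genomes = list(df.columns[1:])
    enzymes = [canonical_enzyme(x) for x in df[enzyme_col]]
    out = []
    for g in genomes:
        present = []
        for enz, cell in zip(enzymes, df[g]):
            token = normalise_label("" if pd.isna(cell) else cell)
            if token in _PRESENT_TOKENS:
                present.append(enz)
            elif token not in _ABSENT_TOKENS:
                raise ValueError(f"unrecognised presence cell {cell!r} for "
                                 f"{enz!r} in genome {g!r}")
        out.append(EnzymeInventory(genome_id=str(g), present_enzymes=frozenset(present)))
    return out


def load_rules(path: str | Path | None = None, ruleset: str = "default") -> PathwayRuleSet:
    """Load a named rule set from YAML (packaged rules when path is None)."""
    if path is None:
        ref = resources.files("sczra").joinpath("data/fermentation_pathway_rules.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    sets = raw["rulesets"]
    if ruleset not in sets:
        raise KeyError(f"no ruleset {ruleset!r}; available: {sorted(sets)}")
    return PathwayRuleSet(version=str(raw.get("version", "unversioned")) + f"/{ruleset}",
                          products=sets[ruleset])


def packaged_inventory_path() -> Path:
    """Path of the packaged three-MAG enzyme inventory fixture."""
    return Path(str(resources.files("sczra").joinpath(
        "data/fermentation_enzyme_inventory.tsv")))


# --------------------------------------------------------------------------
# evaluation and reporting
# --------------------------------------------------------------------------

def evaluate_products(inventory: EnzymeInventory,
                      rules: PathwayRuleSet) -> dict[str, bool]:
    """Evaluate every product rule over the genome's presence set."""
    return {product: _eval_expr(expr, inventory.present_enzymes)
            for product, expr in rules.products.items()}


def complete_products(inventory: EnzymeInventory, rules: PathwayRuleSet) -> set[str]:
    return {p for p, ok in evaluate_products(inventory, rules).items() if ok}


def completeness_report(inventories: Sequence[EnzymeInventory],
                        rules: PathwayRuleSet, path: str | Path) -> pd.DataFrame:
    """Write a genome × product complete/incomplete matrix as TSV."""
    products = list(rules.products)
    rows = []
    for inv in inventories:
        calls = evaluate_products(inv, rules)
        rows.append({"genome_id": inv.genome_id,
                     **{p: ("complete" if calls[p] else "incomplete")
                        for p in products}})
    df = pd.DataFrame(rows, columns=["genome_id"] + products)
    with open(path, "w") as fh:
        fh.write(f"# pathway completeness calls (ruleset {rules.version})\n")
        df.to_csv(fh, sep="\t", index=False)
    return df
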