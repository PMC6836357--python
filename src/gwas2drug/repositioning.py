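"""Sign-logic drug repositioning from ligand-target mechanism tables.

Ligand-target pairs (Guide-to-PHARMACOLOGY-shaped exports) are filtered to
human, non-endogenous, unambiguous mechanisms; each surviving pair gets a ±1
drug-gene sign from a controlled mechanism vocabulary; the drug-phenotype
relationship is the product of the drug-gene sign and the ±1 gene-phenotype
direction from subnetwork enrichment. Candidates are the +1 products only
(expected to enhance the phenotype, here height).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "POSITIVE_ACTIONS",
    "POSITIVE_TYPES",
    "NEGATIVE_ACTIONS",
    "NEGATIVE_TYPES",
    "REMOVED_ACTIONS",
    "UnknownMechanismError",
    "filter_pairs",
    "sign_drug_gene",
    "sign_pairs",
    "infer",
    "select_candidates",
    "repurpose",
]

POSITIVE_ACTIONS = frozenset(
    {"activation", "agonist", "biased agonist", "full agonist", "partial agonist", "positive"}
)
POSITIVE_TYPES = frozenset({"activator", "agonist"})
NEGATIVE_ACTIONS = frozenset(
    {
        "antagonist",
        "feedback inhibition",
        "inhibition",
        "inverse agonist",
        "irreversible inhibition",
        "negative",
        "pore blocker",
        "slows inactivation",
        "voltage-dependent inhibition",
    }
)
NEGATIVE_TYPES = frozenset({"antagonist", "channel blocker", "gating inhibitor", "inhibitor"})
REMOVED_ACTIONS = frozenset({"binding", "mixed", "neutral"})

_LIGAND_COLS = ("ligand", "gene", "species", "endogenous", "action", "type", "primary_target")


class UnknownMechanismError(ValueError):
    """Neither action nor type matches the sign vocabulary."""


def _norm(x: object) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else str(x).strip().lower()


def _parse_bool(x: object) -> bool | None:
    s = _norm(x)
    if s in ("true", "t", "1", "yes", "y"):
        return True
    if s in ("false", "f", "0", "no", "n"):
        return False
    return None  # unknown


def filter_pairs(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-level mechanism-table filter.

    Keeps rows that are (1) human, (2) non-endogenous, (3) carry a non-empty
    action and type with the action outside the uninformative set
    {binding, mixed, neutral}, and (4) name a distinct gene symbol. Rows
    listing multiple symbols (separated by '|' or ';') are split into one row
    per symbol and flagged ``split_multi``. Returns (kept, dropped-with-reason).
    """
    missing = set(_LIGAND_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"ligand table misses columns: {sorted(missing)}")
    kept_rows, dropped_rows = [], []
    for row in table.itertuples(index=False):
        rec = {
            "ligand": str(row.ligand).strip(),
            "gene": str(row.gene).strip(),
            "species": _norm(row.species),
            "endogenous": _parse_bool(row.endogenous),
            "action": _norm(row.action),
            "type": _norm(row.type),
            "primary_target": _parse_bool(row.primary_target),
        }
        reason = None
        if rec["species"] != "human":
            reason = "non_human"
        elif rec["endogenous"] is not False:
            reason = "endogenous_or_unknown"
        elif not rec["action"] or not rec["type"]:
            reason = "unclear_mechanism"
        elif rec["action"] in REMOVED_ACTIONS:
            reason = "uninformative_action"
        elif not rec["gene"] or rec["gene"].lower() in ("na", "nan", "none"):
            reason = "no_gene_symbol"
        if reason:
            dropped_rows.append({**rec, "reason": reason})
            continue
        symbols = [g.strip() for g in rec["gene"].replace(";", "|").split("|") if g.strip()]
        for sym in symbols:
            kept_rows.append({**rec, "gene": sym, "split_multi": len(symbols) > 1})
    kept = pd.DataFrame(kept_rows, columns=[*_LIGAND_COLS, "split_multi"])
    dropped = pd.DataFrame(dropped_rows, columns=[*_LIGAND_COLS, "reason"])
    return kept, dropped


def sign_drug_gene(action: str, mech_type: str) -> int:
    """±1 from the mechanism vocabulary; the action is consulted first, the
    type only when the action is outside both lists."""
    a, t = _norm(action), _norm(mech_type)
    if a in REMOVED_ACTIONS:
        raise ValueError(f"uninformative action {action!r} must be filtered out first")
    if a in POSITIVE_ACTIONS:
        return 1
    if a in NEGATIVE_ACTIONS:
        return -1
    if t in POSITIVE_TYPES:
        return 1
    if t in NEGATIVE_TYPES:
        return -1
    raise UnknownMechanismError(f"no sign for action={action!r}, type={mech_type!r}")


def sign_pairs(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign drug-gene signs to filtered pairs.

    Unknown mechanisms are dropped with a reason rather than failing the run.
    Ligand-gene combinations appearing with both signs are kept and flagged
    ``conflicting``.
    """
    signed_rows, dropped_rows = [], []
    for row in pairs.itertuples(index=False):
        try:
            sign = sign_drug_gene(row.action, row.type)
        except UnknownMechanismError:
            dropped_rows.append({**row._asdict(), "reason": "unknown_mechanism"})
            continue
        signed_rows.append({**row._asdict(), "drug_gene_sign": sign})
    signed = pd.DataFrame(
        signed_rows, columns=[*pairs.columns, "drug_gene_sign"]
    )
    if len(signed):
        n_signs = signed.groupby(["ligand", "gene"])["drug_gene_sign"].transform("nunique")
        signed["conflicting"] = n_signs > 1
    else:
        signed["conflicting"] = pd.Series(dtype=bool)
    dropped = pd.DataFrame(dropped_rows, columns=[*pairs.columns, "reason"])
    return signed, dropped


def infer(signed: pd.DataFrame, gene_phenotype: dict[str, int]) -> pd.DataFrame:
    """drug-phenotype sign = drug-gene sign x gene-phenotype sign.

    Pairs whose gene carries no gene-phenotype direction are skipped.
    """
    rows = []
    for row in signed.itertuples(index=False):
        if row.gene not in gene_phenotype:
            continue
        gp = int(gene_phenotype[row.gene])
        if gp not in (1, -1):
            raise ValueError(f"gene-phenotype sign must be ±1, got {gp} for {row.gene!r}")
        rows.append(
            {
                "ligand": row.ligand,
                "gene": row.gene,
                "drug_gene_sign": int(row.drug_gene_sign),
                "gene_phenotype_sign": gp,
                "drug_phenotype_sign": int(row.drug_gene_sign) * gp,
                "primary_target": row.primary_target,
                "conflicting": bool(getattr(row, "conflicting", False)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ligand", "gene", "drug_gene_sign", "gene_phenotype_sign",
            "drug_phenotype_sign", "primary_target", "conflicting",
        ],
    )


def select_candidates(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep drug-phenotype +1 calls only, primary targets first.

    Unknown primary-target status sorts with non-primary but never excludes
    a candidate.
    """
    out = calls[calls["drug_phenotype_sign"] == 1].copy()
    out["_primary"] = out["primary_target"].apply(lambda v: bool(v) if v is not None else False)
    out = out.sort_values(["_primary", "ligand", "gene"], ascending=[False, True, True])
    return out.drop(columns="_primary").reset_index(drop=True)


def repurpose(
    table: pd.DataFrame, gene_phenotype: dict[str, int]
) -> dict[str, pd.DataFrame]:
    """filter -> sign -> infer -> select, returning every stage."""
    pairs, dropped_filter = filter_pairs(table)
    signed, dropped_sign = sign_pairs(pairs)
    calls = infer(signed, gene_phenotype)
    candidates = select_candidates(calls)
    return {
        "pairs": pairs,
        "signed": signed,
        "calls": calls,
        "candidates": candidates,
        "dropped": pd.concat([dropped_filter, dropped_sign], ignore_index=True),
    }
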