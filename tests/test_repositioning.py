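"""Mechanism filtering, sign vocabulary, and the four-case sign product."""

import itertools

import pandas as pd
import pytest

from gwas2drug.repositioning import (
    NEGATIVE_ACTIONS,
    NEGATIVE_TYPES,
    POSITIVE_ACTIONS,
    POSITIVE_TYPES,
    REMOVED_ACTIONS,
    UnknownMechanismError,
    filter_pairs,
    infer,
    repurpose,
    select_candidates,
    sign_drug_gene,
    sign_pairs,
)


def _table(rows):
    cols = ["ligand", "gene", "species", "endogenous", "action", "type", "primary_target"]
    return pd.DataFrame(rows, columns=cols)


GOOD = ("L1", "G1", "Human", "false", "agonist", "agonist", "true")


def test_filter_keeps_clean_human_rows():
    kept, dropped = filter_pairs(_table([GOOD]))
    assert len(kept) == 1 and len(dropped) == 0
    assert kept.iloc[0]["action"] == "agonist" and bool(kept.iloc[0]["primary_target"])


@pytest.mark.parametrize(
    "row, reason",
    [
        (("L", "G", "Rat", "false", "agonist", "agonist", ""), "non_human"),
        (("L", "G", "Human", "true", "agonist", "agonist", ""), "endogenous_or_unknown"),
        (("L", "G", "Human", "false", "", "agonist", ""), "unclear_mechanism"),
        (("L", "G", "Human", "false", "agonist", "", ""), "unclear_mechanism"),
        (("L", "G", "Human", "false", "binding", "agonist", ""), "uninformative_action"),
        (("L", "G", "Human", "false", "mixed", "inhibitor", ""), "uninformative_action"),
        (("L", "G", "Human", "false", "neutral", "inhibitor", ""), "uninformative_action"),
        (("L", "", "Human", "false", "agonist", "agonist", ""), "no_gene_symbol"),
    ],
)
def test_filter_drop_reasons(row, reason):
    kept, dropped = filter_pairs(_table([row]))
    assert len(kept) == 0
    assert dropped.iloc[0]["reason"] == reason


def test_multi_symbol_rows_split_and_flagged():
    kept, _ = filter_pairs(_table([("L", "GA|GB", "Human", "false", "agonist", "agonist", "")]))
    assert sorted(kept["gene"]) == ["GA", "GB"]
    assert kept["split_multi"].all()


@pytest.mark.parametrize("action", sorted(POSITIVE_ACTIONS))
def test_positive_actions_sign(action):
    assert sign_drug_gene(action, "unclassified") == 1


@pytest.mark.parametrize("action", sorted(NEGATIVE_ACTIONS))
def test_negative_actions_sign(action):
    assert sign_drug_gene(action, "unclassified") == -1


@pytest.mark.parametrize("mech_type", sorted(POSITIVE_TYPES))
def test_positive_types_sign(mech_type):
    assert sign_drug_gene("unlisted action", mech_type) == 1


@pytest.mark.parametrize("mech_type", sorted(NEGATIVE_TYPES))
def test_negative_types_sign(mech_type):
    assert sign_drug_gene("unlisted action", mech_type) == -1


def test_unknown_mechanism_raises_and_is_dropped_in_bulk():
    with pytest.raises(UnknownMechanismError):
        sign_drug_gene("allosteric modulator", "unclassified")
    kept, _ = filter_pairs(
        _table([GOOD, ("L2", "G2", "Human", "false", "weird", "unclassified", "")])
    )
    signed, dropped = sign_pairs(kept)
    assert list(signed["ligand"]) == ["L1"]
    assert dropped.iloc[0]["reason"] == "unknown_mechanism"


def test_removed_actions_never_signed():
    for action in REMOVED_ACTIONS:
        kept, _ = filter_pairs(_table([("L", "G", "Human", "false", action, "agonist", "")]))
        assert len(kept) == 0  # the sign stage can never see these actions
        with pytest.raises(ValueError, match="filtered out first"):
            sign_drug_gene(action, "agonist")


def test_conflicting_ligand_gene_pairs_flagged():
    kept, _ = filter_pairs(
        _table(
            [
                ("L", "G", "Human", "false", "agonist", "agonist", ""),
                ("L", "G", "Human", "false", "antagonist", "antagonist", ""),
            ]
        )
    )
    signed, _ = sign_pairs(kept)
    assert signed["conflicting"].all()
    assert sorted(signed["drug_gene_sign"]) == [-1, 1]


def _signed(pairs):
    return pd.DataFrame(
        [
            {"ligand": l, "gene": g, "species": "human", "endogenous": False,
             "action": a, "type": t, "primary_target": p, "split_multi": False,
             "drug_gene_sign": s, "conflicting": False}
            for l, g, a, t, p, s in pairs
        ]
    )


def test_sign_product_truth_table():
    """All four drug-gene x gene-phenotype combinations, exhaustively."""
    for dg, gp in itertools.product((1, -1), repeat=2):
        signed = _signed([("L", "G", "x", "y", True, dg)])
        calls = infer(signed, {"G": gp})
        assert len(calls) == 1
        assert calls.iloc[0]["drug_phenotype_sign"] == dg * gp


def test_infer_skips_unmapped_genes_and_negation_flips_products():
    signed = _signed(
        [("L1", "G1", "a", "t", True, 1), ("L2", "G2", "a", "t", False, -1),
         ("L3", "G3", "a", "t", None, 1)]
    )
    gp = {"G1": 1, "G2": -1}
    calls = infer(signed, gp)
    assert sorted(calls["ligand"]) == ["L1", "L2"]  # G3 absent from the map
    flipped = infer(signed, {g: -d for g, d in gp.items()})
    merged = calls.merge(flipped, on=["ligand", "gene"], suffixes=("", "_neg"))
    assert (merged["drug_phenotype_sign"] == -merged["drug_phenotype_sign_neg"]).all()


def test_candidate_selection_plus_one_only_primary_first():
    signed = _signed(
        [("L_neg", "G1", "a", "t", False, -1), ("L_pos", "G1", "a", "t", False, 1),
         ("L_prim", "G2", "a", "t", True, 1), ("L_unk", "G3", "a", "t", None, 1)]
    )
    calls = infer(signed, {"G1": 1, "G2": 1, "G3": 1})
    cand = select_candidates(calls)
    assert set(cand["ligand"]) == {"L_pos", "L_prim", "L_unk"}  # -1 product excluded
    assert cand.iloc[0]["ligand"] == "L_prim"  # primary targets first
    assert (cand["drug_phenotype_sign"] == 1).all()
    # candidates partition infer output by sign
    assert len(cand) + (calls["drug_phenotype_sign"] == -1).sum() == len(calls)
    assert len(select_candidates(calls.iloc[0:0])) == 0


def test_repurpose_composes_stages():
    table = _table(
        [
            GOOD,  # agonist on +1 gene -> candidate
            ("L2", "G1", "Human", "false", "inhibition", "inhibitor", "false"),
            ("L3", "G9", "Human", "false", "agonist", "agonist", "false"),  # unmapped
            ("L4", "G1", "Rat", "false", "agonist", "agonist", "false"),
        ]
    )
    stages = repurpose(table, {"G1": 1})
    assert list(stages["candidates"]["ligand"]) == ["L1"]
    assert set(stages["dropped"]["ligand"]) == {"L4"}
    assert len(stages["calls"]) == 2
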