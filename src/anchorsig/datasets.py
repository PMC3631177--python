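"""Bundled reference tables from a published NSCLC anchor-gene screen.

Three small TSVs transcribed from published ranked tables of a GAPDH-anchored
co-expression analysis of non-small cell lung cancer on the Affymetrix U133
Plus 2.0 platform:

* ``nsclc_top26`` — the 26 top-ranked up-regulated genes with anchor
  correlation r >= 0.72 (columns: gene title, symbol, probe, r,
  GO definition, T/C, one-tailed t-test p).
* ``foxm1_pathway`` — 28 FoxM1-pathway genes with the same statistics.
* ``glycolysis_gluconeogenesis`` — the 10 glycolysis steps and 3
  gluconeogenesis bypass steps with T/C ratios and p-values (the anchor,
  GAPDH, is step G6, probe 212581_x_at).

They serve as worked-example inputs and regression fixtures: screening
thresholds and enrichment arithmetic can be validated against counts read
directly off the printed columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# Platform background used alongside these tables: the U133 Plus 2.0 array
# carries 54,613 probe sets, of which 2,044 are annotated to the Gene
# Ontology biological-process term "cell cycle".
U133_PLUS2_PROBES = 54613
U133_PLUS2_CELL_CYCLE = 2044

GAPDH_PROBE = "212581_x_at"


def _load(name: str) -> pd.DataFrame:
    with resources.files("anchorsig.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_top_ranked_table() -> pd.DataFrame:
    """Top-ranked anchor-correlated genes (26 rows, r >= 0.72)."""
    return _load("nsclc_top26.tsv")


def load_foxm1_pathway_table() -> pd.DataFrame:
    """FoxM1-pathway genes with anchor correlations (28 rows)."""
    return _load("foxm1_pathway.tsv")


def load_glycolysis_table() -> pd.DataFrame:
    """Glycolysis/gluconeogenesis step table (19 rows)."""
    return _load("glycolysis_gluconeogenesis.tsv")


def as_screen_records(table: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Convert a bundled ranked table to screen-record form.

    Produces the columns ``apply_thresholds`` expects (probe_id, gene_symbol,
    r, tc_ratio, p_value, direction, ...), deriving the regulation direction
    from T/C and p with the same rule the screen uses.
    """
    rec = pd.DataFrame(
        {
            "probe_id": table["probe"],
            "gene_symbol": table["symbol"],
            "r": table["r"] if "r" in table.columns else float("nan"),
            "n_pairs": 330,  # full-cohort tables: 174 tumors + 156 controls
            "tc_ratio": table["tc"].astype(float),
            "p_value": table["p"].astype(float),
        }
    )
    direction = []
    for tc, p in zip(rec["tc_ratio"], rec["p_value"]):
        if tc > 1 and p <= p_max:
            direction.append("up")
        elif tc < 1 and p <= p_max:
            direction.append("down")
        else:
            direction.append("flat")
    rec["direction"] = direction
    if "go_definition" in table.columns:
        rec["categories"] = table["go_definition"]
    return rec
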