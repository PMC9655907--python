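"""Biochemical composition of the strain panel with folds versus the wild strain.

Uses the packaged protein/carbohydrate/lipid %DW table; mg/gDW = %DW × 10.
"""

from pathlib import Path

from algadiesel import datasets
from algadiesel.assays import composition_table

if __name__ == "__main__":
    comp = datasets.load_composition().reset_index().melt(
        id_vars="strain", var_name="analyte", value_name="pct"
    )
    comp["analyte"] = comp["analyte"].str.replace("_pct_dw", "", regex=False)
    comp["value"] = comp["pct"] * 10.0
    table = composition_table(comp[["strain", "analyte", "value"]]).round(3)
    out = Path("results/composition.csv")
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    top = table.loc[table["analyte"] == "lipid"].nlargest(1, "fold_vs_wild").iloc[0]
    print(f"\nhighest lipid gain: {top['strain']} at {top['pct_dw']}%DW "
          f"({top['pct_change_vs_wild']:.1f}% over wild) → {out}")
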