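"""Generate one synthetic input set for every pipeline stage.

Writes growth, screening, FAME-profile and assay CSVs (plus truth.json)
under results/simulated/ so the later drivers can run end-to-end without
any external data. All randomness derives from one seed.
"""

from click.testing import CliRunner

from algadiesel.cli import main

SEED = 1
OUTDIR = "results/simulated"

if __name__ == "__main__":
    res = CliRunner().invoke(main, ["simulate", "--seed", str(SEED), "--outdir", OUTDIR])
    print(res.output.strip())
    if res.exit_code:
        raise SystemExit(res.exit_code)
    print(f"seed {SEED}: growth curve, dose-mortality table, 3 FAME profiles and "
          f"one assay set written with ground truth alongside.")
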