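"""Shared configuration for the numbered analysis drivers."""

from pathlib import Path

from mixedbeam.pipeline import RunConfig

OUT_DIR = Path(__file__).resolve().parent.parent / "results"

#: Interaction factor of the demonstration study: observed/expected
#: mixed-beam slope ratio of 1.4, the size of effect the donors showed.
DEMO_THETA = 1.4
DEMO_SEED = 20201109


def run_config() -> RunConfig:
    cfg = RunConfig(
        out_dir=str(OUT_DIR),
        seed=DEMO_SEED,
        synthetic={"interaction_theta": DEMO_THETA},
    )
    cfg.ct_table = str(OUT_DIR / "ct_table.csv")
    cfg.metaphase_table = str(OUT_DIR / "metaphase_table.csv")
    return cfg
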