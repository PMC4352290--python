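"""Single-command study replica: simulate -> preprocess -> ERP -> TFR -> stats.

Runs the configuration-driven pipeline at reduced scale (6 participants,
20 trials/cell, strong injected effects) and prints the headline lines of
the generated report.  Equivalent CLI:

    sfgamma run --seed 7 --out demo_run
"""

from pathlib import Path

from sfgamma import RunConfig, run_pipeline

cfg = RunConfig(
    n_participants=6,
    trials_per_cell=20,
    seed=7,
    out_dir="scratch_demo_run",
    truth={"noise_scale_uv": 2.0, "lat_sd_between": 3.0},  # strong-effect demo
)
run_dir = run_pipeline(cfg)

print(f"outputs in {run_dir}/: "
      f"{', '.join(sorted(p.name for p in Path(run_dir).iterdir()))}\n")
report = (run_dir / "report.txt").read_text()
for block in report.split("\n\n"):
    block = block.strip("\n")
    head = block.splitlines()[0] if block.splitlines() else ""
    if head.startswith("ANOVA on") and head.split()[-1] in (
        "N1_mean_amp", "tgba",
    ):
        print(block, "\n")
print("\n(the report also contains cell-mean tables per measure; "
      "rerunning with the same seed reproduces every file byte-for-byte)")
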