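"""The whole procedure as one configured, reproducible pipeline run.

Writes a synthetic dataset to disk, builds a RunConfig, executes
read -> aggregate -> stability x subsets -> consensus -> expression, and
lists the report tables (all plain TSV, regenerable from config.yaml).
"""

import tempfile
from pathlib import Path

from refstab import paper_like_fixture, write_ct_table
from refstab.pipeline import RunConfig, run_pipeline

workdir = Path(tempfile.mkdtemp(prefix="refstab_"))
table, truth = paper_like_fixture(seed=1)
write_ct_table(table, workdir / "ct_long.csv")

candidates = truth.roles.index[truth.roles != "target"].tolist()

cfg = RunConfig(
    ct_path=str(workdir / "ct_long.csv"),
    candidate_genes=candidates,
    target_genes=["SsCS"],
    normalizers=[["SsCDC6", "SsNCBP2"], ["SsPP2A"]],
    outdir=str(workdir / "report"),
)
report = run_pipeline(cfg)

print(f"chosen reference pair: {report.chosen_pair}")
print(f"recommended reference count per subset: {report.recommended_n}")
print("\nconsensus (all samples), top 5:")
print(report.consensus["all"].table.sort_values("final_rank").head().round(3).to_string())

print(f"\nreport tables under {cfg.outdir}:")
for path in sorted(Path(cfg.outdir).iterdir()):
    print(" ", path.name)
# Per-treatment subsets get their own stability tables, mirroring how such
# studies analyze each stress separately plus a pooled "all" group.
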