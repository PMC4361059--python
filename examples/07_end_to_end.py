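"""The whole pipeline in one call: simulate, call, annotate, report.

Writes per-lesion VCFs, a burden table, spectrum / clonality /
validation / overlap reports and a manifest with content hashes;
re-running with the same seed reproduces every byte.
"""

import tempfile
from pathlib import Path

from polyclone.config import PipelineConfig
from polyclone.pipeline import run_all
from polyclone.simulate import SimParams

cfg = PipelineConfig(
    seed=1,
    sim=SimParams(n_patients=2, lesions_per_patient=2, n_sites=2000, seed=1),
)
out = Path(tempfile.mkdtemp(prefix="polyclone_"))
bundle = run_all(cfg, str(out))

print(f"reports in {out}:")
for f in sorted(p.name for p in out.iterdir()):
    print(" ", f)
print()
print((out / "lesion_metrics.tsv").read_text())
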