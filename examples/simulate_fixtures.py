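"""Write the full synthetic fixture set with its ground truth.

Generates every input the pipeline consumes — time course, DEG table,
background, gene sets, toy annotation, alignments, a published set —
into a directory, together with truth.json describing exactly what was
planted. Re-running with the same seed reproduces the files byte for
byte.
"""

import json
import sys
from pathlib import Path

from stemstat.simgen import (
    DEGConfig,
    GenomeConfig,
    SetsConfig,
    SimConfig,
    TimecourseConfig,
    write_fixture,
)

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("scratch/fixture")
cfg = SimConfig(
    seed=1,
    timecourse=TimecourseConfig(effects=(0, 0, 3, 3, 3)),
    deg=DEGConfig(n_genes=5000, n_true=1000),
    sets=SetsConfig(n_sets=10, set_size=200, rho=3.0, n_enriched=2),
    genome=GenomeConfig(),
)
truth = write_fixture(cfg, outdir)

print(f"wrote fixture to {outdir}/:")
for f in sorted(p.name for p in outdir.iterdir()):
    print(" ", f)
print("planted:", json.dumps(
    {k: truth["genome"][k] for k in ("n_unique", "n_ambiguous", "n_filtered")}
))
print("true DEGs:", len(truth["deg"]["true_deg_ids"]))

# truth.json lets any downstream check compare what an analysis recovers
# against what was actually planted.
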