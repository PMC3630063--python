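"""Generate a complete synthetic drought small-RNA study with ground truth.

Builds a genome with 20 planted miRNA hairpins, two sRNA libraries
(control/drought), a transcriptome with target sites, and a degradome
library, then prints where everything landed.
"""

from plantmir import SimulationConfig, write_fixture_bundle
from plantmir.simulate import GroundTruth
from pathlib import Path
import json

outdir = Path("scratch/example_bundle")
manifest = write_fixture_bundle(outdir, SimulationConfig(seed=1))
print("wrote:", ", ".join(manifest["files"]))

truth = GroundTruth.from_json((outdir / "truth.json").read_text())
m = truth.mirnas[0]
print(f"\nfirst planted miRNA: {m.name}")
print(f"  mature  {m.mature}")
print(f"  star    {m.star}")
print(f"  locus   {m.scaffold}:{m.start}:{m.end}:{m.strand}  (LP = {m.end - m.start + 1} nt)")
print(f"  arm     {m.arm}")
print(f"\n{len(truth.mirnas)} hairpins planted, {len(truth.target_sites)} target sites,")
print(f"{len(truth.contaminants)} structural-RNA loci, {len(truth.sirna_pairs)} siRNA duplex pairs.")
# The locus string is 1-based inclusive, so LP always equals end - start + 1;
# every planted mature/star pair forms a duplex with 2-nt 3' overhangs.
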