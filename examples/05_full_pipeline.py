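"""End-to-end run: simulate -> FC -> bands -> networks -> structure-function.

Runs the whole analysis on a small synthetic dataset with one configuration
object and prints the headline numbers of every stage. With ``output_dir``
set, all artifacts (HDF5 epochs, TSV matrices, JSON tables, manifest) are
written to disk.
"""

import tempfile
from pathlib import Path

from rhythmnet import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        seed=7,
        n_areas=4,
        sites_per_area=2,
        n_epochs=100,
        n_randomizations=50,
        gamma_points=8,
        louvain_reps=3,
        n_perm=200,
        output_dir=tmp,
    )
    results = run_pipeline(cfg)

    print("bands defined blindly from per-site spectral peaks:")
    for b in results["bands"]:
        print(f"  {b.name:10s} {b.pf:5.1f} +/- {b.fwhm / 2:.1f} Hz")

    print("\ndistinctiveness between band-specific coherence networks:")
    for (b1, b2), d in results["distinctiveness"].items():
        print(f"  {b1} vs {b2}: D = {d.d:.2f} (partialized for distance)")

    mod = results["modularity"]
    print(f"\nconsensus modularity: {len(set(mod.partition))} modules, "
          f"q = {mod.q:.3f}")

    print(f"\nEDR fit on synthetic anatomy: lambda = {results['edr'].lam:.3f}/mm")
    print("GC ~ FLNe regression per band:")
    for band, reg in results["fc_flne"].items():
        print(f"  {band:10s} slope {reg.slope:+.2f}  r^2 {reg.r2:.2f}  "
              f"fold change {reg.fold_change:.1f}")

    wrote = sorted(p.name for p in Path(tmp).iterdir())
    print(f"\nartifacts written: {', '.join(wrote)}")
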