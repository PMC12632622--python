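"""Call aneuploidies and segmental amplifications from read depth.

Simulates a clone with a trisomy of chr2 and a second clone with a
100-kb amplification on chr7, computes per-chromosome copy ratios
(median chromosome depth / median genome depth, rounded to the nearest
0.5) and scans 1-kb bins for segmental events.
"""

from poolcomp.karyotype import call_karyotype, call_segments, coverage_profile
from poolcomp.simdata import CloneGenomeSpec, Event, make_clone_genomes

sizes = {f"chr{i}": 50_000 for i in range(1, 7)}
sizes["chr7"] = 700_000
spec = CloneGenomeSpec(
    sizes, n_het_sites=10, mean_depth=30.0, depth_noise="poisson",
    events=[
        Event("clone1", "aneuploidy", "chr2", 1, 50_000, copies=3),
        Event("clone2", "segmental_amp", "chr7", 100_001, 200_000, copies=3),
    ],
)
_, depth_tables, _ = make_clone_genomes(spec, n_clones=2, seed=6)

prof1 = coverage_profile(depth_tables["clone1"])
call1 = call_karyotype(prof1)
print(f"clone1 genome median depth {prof1.genome_median:.0f}; copy ratios:")
print("  " + ", ".join(f"{c}={r}" for c, r in call1.ratios.items()))
print(f"  aneuploid: {call1.aneuploid_chromosomes()} (1.5 = three copies on a diploid)")

prof2 = coverage_profile(depth_tables["clone2"])
call2 = call_karyotype(prof2)
segs = call_segments(prof2, call2.ratios)
print(f"\nclone2 whole-chromosome ratios all euploid: "
      f"{set(call2.ratios.values()) == {1.0}}")
print("segmental events (>= 20 consecutive 1-kb bins deviating >= 0.4):")
print(segs.to_string(index=False))
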