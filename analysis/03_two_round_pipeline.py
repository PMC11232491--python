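#!/usr/bin/env python
"""Run the two-round cause-effect pipeline on the reference study and
score recovery of the planted probe blocks.

Round 1 clusters the swarm axis of the probe x swarm co-citation matrix
(UPGMA on cosine, CCSV cut at 0.92) and keeps clusters containing a
pathway-receptor swarm; round 2 re-counts against the selected swarms
and cuts the probe axis at CCSV 0.76 into disease groups.  The grouping
is compared with the planted probe-pathway blocks via the adjusted Rand
index, across seeds 0-9.  Writes per-seed artifacts and a summary under
results/pipeline/.
"""

from pathlib import Path

from sklearn.metrics import adjusted_rand_score

from swarmcite import run_pipeline, validate_config

out = Path("results/pipeline")
out.mkdir(parents=True, exist_ok=True)

rows = []
for seed in range(10):
    cfg = validate_config({"simulate": {}, "output_dir": str(out / f"seed{seed}")})
    result = run_pipeline(cfg, seed=seed)
    probes = sorted(result.corpus.probe_registry)
    blocks = result.truth.probe_blocks()
    ari = adjusted_rand_score(
        [str(blocks[p]) for p in probes], result.grouping.labels_for(probes)
    )
    rows.append((seed, len(result.swarms), len(result.round1_clusters),
                 len(result.interactome.clusters), len(result.interactome.proteins),
                 len(result.grouping.groups), ari))
    print(f"seed {seed}: {len(result.swarms)} swarms, "
          f"{len(result.round1_clusters)} round-1 clusters "
          f"({len(result.interactome.clusters)} selected, "
          f"{len(result.interactome.proteins)}-protein interactome), "
          f"{len(result.grouping.groups)} disease groups, ARI {ari:.3f}")

with open(out / "summary.tsv", "w") as fh:
    fh.write("seed\tswarms\tround1_clusters\tselected\tinteractome_proteins\tgroups\tari\n")
    for r in rows:
        fh.write("\t".join(f"{x:.3f}" if isinstance(x, float) else str(x) for x in r) + "\n")

successes = sum(1 for r in rows if r[-1] >= 0.9)
print(f"\nplanted-block recovery: ARI >= 0.9 in {successes}/10 seeds "
      f"(mean {sum(r[-1] for r in rows) / 10:.3f})")
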