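"""Scan upstream regions and find cluster-enriched binding motifs.

Every filtered gene's 1000 bp upstream region is scanned for the IUPAC
motif library (presence/absence only).  Motif enrichment per cluster
uses the upper-tail cumulative binomial against the carrier frequency
over the differentially regulated gene set, with the published
thresholds: p < 0.01 and at least 10 carrier genes in the cluster.
"""

import pandas as pd

from _common import RESULTS, SEED, get_world
from mycolink import (
    build_associations,
    condition_profiles,
    enrich_motifs,
    filter_genes,
    kmeans_cluster,
)


def main() -> None:
    world = get_world()
    filtered = filter_genes(world.expr_host, world.flags_host, 0.33)
    profiles = condition_profiles(world.expr_host.loc[filtered],
                                  world.replicate_map, list(world.conditions))
    clusters = kmeans_cluster(profiles, k=9, seed=SEED)

    upstreams = {g: world.upstream_sequences[g] for g in filtered}
    associations = build_associations(upstreams, world.motif_patterns(), filtered)
    rows = []
    for c in clusters:
        for e in enrich_motifs(c.id, c.members, associations,
                               alpha=0.01, min_genes=10):
            rows.append((e.cluster, e.motif, e.n, e.x, round(e.f, 4), e.p, e.passes))
    df = pd.DataFrame(rows, columns=["cluster", "motif", "n", "x", "f", "p", "passes"])
    out = RESULTS / "motif_enrichment.tsv"
    df.to_csv(out, sep="\t", index=False)

    passing = df[df.passes]
    print(f"{len(associations)} motifs scanned over {len(filtered)} upstream regions")
    print(f"{len(passing)} enriched (cluster, motif) pairs at p<0.01 and >=10 carriers:")
    for _, r in passing.iterrows():
        print(f"  {r.cluster}: {r.motif:16s} x={r.x:3d}/{r.n} f={r.f:.3f} p={r.p:.2e}")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
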