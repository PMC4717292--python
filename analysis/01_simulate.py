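"""Generate and export the synthetic interaction world.

Emulates the full study design -- ten host and ten symbiont
transcriptomes over free-living, six interaction time points and
mycorrhizal conditions -- with planted co-regulated clusters, upstream
motifs, sensor complexes, and metabolite-cluster couplings.
"""

from _common import SEED, WORLD_DIR, get_world


def main() -> None:
    world = get_world()
    t = world.ground_truth
    print(f"world (seed {SEED}) exported to {WORLD_DIR}")
    print(f"  host genes:      {len(world.host_genes)} "
          f"({len(t['silent_genes'])} silent)")
    print(f"  symbiont genes:  {len(world.expr_symbiont)}")
    print(f"  planted clusters: {len(t['clusters'])} x "
          f"{world.config.cluster_size} genes")
    print(f"  planted complexes: "
          + ", ".join(f"{c['id']}({len(c['roles'])} in {c['cluster']})"
                      for c in t["complexes"]))
    print(f"  planted metabolite links: "
          + ", ".join(f"{l['metabolite']}->{l['cluster']}({l['sign']:+d})"
                      for l in t["metabolite_links"]))


if __name__ == "__main__":
    main()
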