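"""Degree-based hub screen of a selected gene set on a PPI edge list.

Writes a small STRING-style edge list, ranks genes by network degree,
takes the top hubs and intersects them with a curated reference list
(GenAge-style, one symbol per line, matched case-insensitively).
"""

import tempfile
from pathlib import Path

from mtamo import degree_hubs, intersect_gene_list, read_edge_list

workdir = Path(tempfile.mkdtemp())

edges = workdir / "ppi_edges.tsv"  # synthetic toy network
edges.write_text(
    "protein1\tprotein2\tcombined_score\n"
    "ESR1\tATM\t0.92\nESR1\tEP300\t0.88\nESR1\tPIK3CA\t0.85\n"
    "ESR1\tCDC42\t0.81\nATM\tEP300\t0.77\nEP300\tPIK3CA\t0.74\n"
    "CDC42\tPTK2B\t0.69\nEGF\tPTK2B\t0.66\nEGF\tESR1\t0.41\n"
)
reference = workdir / "aging_reference.txt"
reference.write_text("esr1\natm\ncdc42\nep300\npik3ca\negf\nptk2b\n")

graph = read_edge_list(edges, min_score=0.6)  # drops the 0.41 edge
print(f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges")

result = degree_hubs(graph, k=3)
print("degree ranking:")
for gene, degree in result.ranking:
    print(f"  {gene:<7} degree {degree}")
print(f"top {result.k} hubs: {result.hubs}")

aging = intersect_gene_list(result.hubs, reference)
print(f"hubs present in the aging reference list: {aging}")
print(
    "High-degree nodes are candidate hub genes; the reference intersection "
    "keeps only those with curated aging evidence."
)
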