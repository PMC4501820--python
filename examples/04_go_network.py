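"""GO enrichment of miRNA targets and the overlap-coefficient term network.

A small hand-made regulator→target table and gene→GO annotation: targets of
each DE miRNA are tested for term enrichment (right-tailed hypergeometric,
plus the conservative EASE variant), brain-related terms are kept, and
terms sharing >50% of their smaller target set are linked.
"""

import tempfile
from pathlib import Path

import pandas as pd

from mirdel.gonet import (
    build_network,
    enrich_all,
    export_network,
    filter_targets,
    select_brain_terms,
)

targets = pd.DataFrame(
    [
        ("miR-a", g, "high_confidence")
        for g in ["SYN1", "DLG4", "NRXN1", "GRIN2B", "ACTB", "GAPDH"]
    ]
    + [("miR-b", g, "experimentally_validated") for g in ["SYN1", "DLG4", "SHANK3", "TUBB3"]]
    + [("miR-b", "ALDOA", "moderate")],  # dropped by the confidence filter
    columns=["mirna_id", "gene", "confidence"],
)
universe = {f"GENE{i}" for i in range(40)} | set(targets["gene"])
annotation = {
    "GO:0007268": {"SYN1", "DLG4", "NRXN1", "GRIN2B", "SHANK3"},
    "GO:0050808": {"SYN1", "DLG4", "SHANK3", "NRXN1"},
    "GO:0008152": {"ACTB", "GAPDH", "ALDOA"},
}
term_names = {
    "GO:0007268": "chemical synaptic transmission",
    "GO:0050808": "synapse organization",
    "GO:0008152": "metabolic process",
}

kept = filter_targets(targets)
print(f"targets kept after confidence filter: {len(kept)}/{len(targets)}")
results = enrich_all(kept, annotation, universe, term_names=term_names)
for r in results:
    print(f"{r.mirna_id} x {r.term_name}: k={r.k}/{r.n}, term {r.K}/{r.N}, "
          f"p={r.p_fisher:.4f} (EASE {r.p_ease:.4f})")

selected = select_brain_terms(results)
term_targets = {r.term_id: annotation[r.term_id] & set(kept["gene"]) for r in selected}
net = build_network(selected, term_targets, {"miR-a": "up", "miR-b": "down"})
print(f"\nnetwork: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges "
      f"(term-term edges require overlap coefficient > 0.5)")
outdir = Path(tempfile.mkdtemp(prefix="mirdel_net_"))
export_network(net, outdir / "network.sif", outdir / "network.graphml")
print(f"exported SIF + GraphML to {outdir}")
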