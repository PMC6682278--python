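"""Export a threshold-filtered navigation graph for browser rendering.

Applies the 0.13 probability cutoff to the published chain: edges below
the cutoff are dropped, except that a page which would become visually
isolated keeps its single strongest incoming edge.  Writes d3-style
node-link JSON and GraphViz DOT.
"""

from clickchain import export_dot, export_graph_json, start2cycle_reference_model, threshold_edges

model = start2cycle_reference_model()
edges = threshold_edges(model, cutoff=0.13, keep_max_incoming=True)

kept = [e for e in edges if not e.exception]
rescued = [e for e in edges if e.exception]
print(f"cutoff 0.13: {len(kept)} edges at or above the cutoff, {len(rescued)} rescued:")
for e in rescued:
    print(f"  {e.source} -> {e.target} (p={e.probability:.2f}): "
          "strongest incoming edge of an otherwise isolated page")

strongest = max(edges, key=lambda e: e.probability)
print(f"strongest displayed edge: {strongest.source} -> {strongest.target} "
      f"(p={strongest.probability:.2f})")

export_graph_json(model, edges, "scratch_graph.json")
export_dot(model, edges, "scratch_graph.dot")
print("wrote scratch_graph.json (d3 node-link) and scratch_graph.dot (GraphViz)")
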