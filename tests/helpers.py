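"""Shared test helpers."""

import networkx as nx


class StubNetwork:
    """Hand-built vessel graph for closed-form flow checks."""

    def __init__(self, edges, inlet, outlet):
        self.graph = nx.Graph()
        for a, b, radius, length in edges:
            self.graph.add_edge(a, b, radius=radius, length=length,
                                mother=False, collapsed=False, dead=False,
                                perfused=True, flow=0.0, shear=0.0)
        self.inlet = inlet
        self.outlet = outlet
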