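"""Bundled example networks.

``toy15`` is the 15-node, 19-edge example network used throughout the
package's documentation and tests.  Two loosely connected regions are
bridged by the single 6–8 edge: node 6 is the overall hot spot, while
node 8 earns high closeness/betweenness purely from sitting next to it
on the bridge — the configuration that separates the heatmap ranking
from the classical ones.
"""

from __future__ import annotations

from .graph import Graph

__all__ = ["TOY15_EDGES", "fixture_toy15", "FIXTURES", "load_fixture"]

#: Edge list of the 15-node / 19-edge example network.
TOY15_EDGES: tuple[tuple[int, int], ...] = (
    (1, 3), (2, 3), (3, 4), (3, 5), (3, 6), (3, 7), (4, 5), (5, 6),
    (6, 7), (6, 8), (6, 14), (8, 9), (8, 10), (9, 10), (9, 12),
    (10, 11), (10, 12), (10, 13), (12, 15),
)


def fixture_toy15() -> Graph:
    """The 15-node, 19-edge example network (connected, simple)."""
    return Graph(TOY15_EDGES)


FIXTURES = {"toy15": fixture_toy15}


def load_fixture(name: str) -> Graph:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
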