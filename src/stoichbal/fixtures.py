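"""Bundled toy networks and copy tables, generated programmatically.

Small worked examples used in tests, docs and the `make-fixtures`
subcommand: a balanced competitive chain, the same chain with an
overexpressed middle protein, and a mixed competitive/noncompetitive
network whose balance requires the quadratic program.
"""

from __future__ import annotations

from pathlib import Path

from .network import InterfaceNetwork, write_network

__all__ = [
    "chain_network",
    "chain_copies_balanced",
    "chain_copies_unbalanced",
    "mixed_network",
    "mixed_copies",
    "write_fixtures",
]


def chain_network() -> InterfaceNetwork:
    """Competitive chain A-B-C: B binds both partners with one interface,
    so balance requires B = A + C."""
    return InterfaceNetwork(
        ["A", "B", "C"],
        [("A", "i1"), ("B", "i1"), ("C", "i1")],
        [(("A", "i1"), ("B", "i1")), (("B", "i1"), ("C", "i1"))],
    )


def chain_copies_balanced() -> dict[str, float]:
    return {"A": 50.0, "B": 100.0, "C": 50.0}


def chain_copies_unbalanced() -> dict[str, float]:
    """An excess of B is left over after all possible complexes form."""
    return {"A": 50.0, "B": 160.0, "C": 50.0}


def mixed_network() -> InterfaceNetwork:
    """Four proteins mixing competitive and noncompetitive binding.

    D binds B and C on two separate interfaces (noncompetitive); A binds
    B and C competitively through one interface; balancing couples all
    four copy numbers through the shared interfaces.
    """
    return InterfaceNetwork(
        ["A", "B", "C", "D"],
        [("A", "i1"), ("B", "i1"), ("C", "i1"), ("D", "i1"), ("D", "i2")],
        [
            (("A", "i1"), ("B", "i1")),
            (("A", "i1"), ("C", "i1")),
            (("B", "i1"), ("D", "i1")),
            (("C", "i1"), ("D", "i2")),
        ],
    )


def mixed_copies() -> dict[str, float]:
    return {"A": 100.0, "B": 120.0, "C": 80.0, "D": 60.0}


def _write_copies(path: Path, copies: dict[str, float]) -> None:
    with open(path, "w") as fh:
        for k in sorted(copies):
            fh.write(f"{k}\t{copies[k]:g}\n")


def write_fixtures(outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, net, copies in [
        ("chain_balanced", chain_network(), chain_copies_balanced()),
        ("chain_unbalanced", chain_network(), chain_copies_unbalanced()),
        ("mixed", mixed_network(), mixed_copies()),
    ]:
        np_ = outdir / f"{name}.network.tsv"
        cp = outdir / f"{name}.copies.tsv"
        write_network(net, np_)
        _write_copies(cp, copies)
        paths += [np_, cp]
    return paths
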