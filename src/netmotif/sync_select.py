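"""Propagate node selections across networks via shared names and identity maps.

A selection is a set of shared names.  Propagation computes the closure of
the selected names under every identity map registered on the session
(applied in both directions, transitively to a fixed point) and intersects
the closure with each network's node set.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from netmotif.network_session import Session


class MappingFormatError(ValueError):
    """Raised on a malformed mapping or selection file."""


@dataclass
class Selection:
    """A set of shared names, optionally tagged with the originating network."""

    names: set[str]
    source_network: str | None = None

    def __post_init__(self) -> None:
        self.names = {str(n) for n in self.names}
        if any(not n for n in self.names):
            raise ValueError("selection names must be non-empty strings")


@dataclass
class IdentityMap:
    """A many-to-many correspondence between two name spaces.

    Lookup is symmetric: ``pairs`` stores (name_a, name_b) but propagation
    follows the pairs in both directions.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    spaces: tuple[str, str] = ("a", "b")

    def neighbors(self, name: str) -> set[str]:
        out = set()
        for a, b in self.pairs:
            if a == name:
                out.add(b)
            if b == name:
                out.add(a)
        return out


def _closure(names: Iterable[str], maps: Iterable[IdentityMap]) -> set[str]:
    """Transitive, symmetric closure of *names* under all identity maps."""
    adjacency: dict[str, set[str]] = {}
    for imap in maps:
        for a, b in imap.pairs:
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)
    seen = set(names)
    queue = deque(seen)
    while queue:
        name = queue.popleft()
        for other in adjacency.get(name, ()):
            if other not in seen:
                seen.add(other)
                queue.append(other)
    return seen


def propagate(
    session: Session, selection: Selection, case_insensitive: bool = False
) -> dict[str, set[str]]:
    """Map each network name to the shared names it should select.

    For every network the result is the intersection of the network's node
    set with the closure of the selection under the session's identity maps.
    Matching is exact and case sensitive unless ``case_insensitive`` is set.
    """
    if len(session) == 0:
        raise ValueError("cannot propagate over an empty session")
    closed = _closure(selection.names, session.identity_maps.values())
    result: dict[str, set[str]] = {}
    if case_insensitive:
        closed_folded = {n.casefold() for n in closed}
        for net in session.networks:
            result[net.name] = {n for n in net.nodes if n.casefold() in closed_folded}
    else:
        for net in session.networks:
            result[net.name] = {n for n in net.nodes if n in closed}
    return result


def load_mapping(path, spaces: tuple[str, str] = ("a", "b"), sep: str = "\t") -> IdentityMap:
    """Load a two-column delimited identity-mapping file.

    Blank lines and ``#`` comments are skipped.  A first row whose two cells
    equal the declared space labels (case-insensitively) is treated as a
    header and skipped; anything else with two columns is a mapping pair.
    """
    pairs: set[tuple[str, str]] = set()
    first_data_row = True
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in line.split(sep)]
            if len(cells) != 2 or not all(cells):
                raise MappingFormatError(
                    f"{Path(path).name}:{lineno}: expected 2 columns, got {len(cells)}"
                )
            if (
                first_data_row
                and cells[0].casefold() == spaces[0].casefold()
                and cells[1].casefold() == spaces[1].casefold()
            ):
                first_data_row = False
                continue
            first_data_row = False
            pairs.add((cells[0], cells[1]))
    return IdentityMap(pairs=pairs, spaces=tuple(spaces))


def export_selection(selection: Selection, path) -> None:
    """Write a selection as a flat file: one shared name per line,
    lexicographically sorted, with a trailing newline."""
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(selection.names):
            fh.write(name + "\n")


def read_selection(path, source_network: str | None = None) -> Selection:
    """Read a flat selection file (one shared name per line) back in."""
    names: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            name = raw.strip()
            if name and not name.startswith("#"):
                names.add(name)
    return Selection(names=names, source_network=source_network)
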