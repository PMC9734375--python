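"""Sample registry: the derivation forest of cell samples.

Every tracked sample is a node in a forest whose roots are transfection
designators. Clone designation (a well observed to hold an edited colony)
and flow sorting each derive a child whose name extends the parent's —
so the parent/child relation is readable off the names themselves, and a
chain of sorts forms a path ``base → base_C6 → base_C6_Sort1 → ...``.

The registry is driven by ledger records (:meth:`SampleRegistry.apply_record`)
and is a pure function of the entry sequence: replaying the same records
reproduces it exactly. Discontinuation flips a status flag; nodes are
never deleted (the ledger keeps full history).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import LookupError_, UniquenessError
from .naming import (
    SampleName,
    WellAddress,
    derive_clone_name,
    derive_sort_name,
    format_name,
    parse_name,
)

ACTIVE = "active"
DISCONTINUED = "discontinued"


@dataclass
class SampleNode:
    name: str
    parsed: SampleName
    parent: Optional[str]
    created_seq: int
    status: str = ACTIVE


@dataclass
class SampleRegistry:
    """Name → node mapping; insertion order is creation order."""

    _nodes: dict[str, SampleNode] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[SampleNode]:
        return iter(self._nodes.values())

    def node(self, name: str) -> SampleNode:
        try:
            return self._nodes[name]
        except KeyError:
            raise LookupError_(f"sample {name!r} is not registered") from None

    # --- creation -------------------------------------------------------

    def add_root(self, name: SampleName, seq: int) -> SampleNode:
        """Register a transfection designator as a new root."""
        if name.well is not None or name.sort_index is not None:
            raise UniquenessError(
                f"{format_name(name)!r} carries suffixes; roots must be base "
                "transfection designators"
            )
        return self._add(name, parent=None, seq=seq)

    def _add(self, name: SampleName, parent: Optional[str], seq: int) -> SampleNode:
        text = format_name(name)
        if text in self._nodes:
            raise UniquenessError(f"sample {text!r} already registered")
        node = SampleNode(text, name, parent, seq)
        self._nodes[text] = node
        return node

    def apply_record(self, record, new_clone_well: Optional[WellAddress] = None):
        """Update the registry for one validated ledger record.

        ``Transfect`` creates a root; a record carrying a clone-designation
        well creates a clone child of the record's sample; ``Sort`` derives
        the next sort name from the record's sample; ``Discontinue`` flips
        the sample's status. All other activities leave the forest alone.
        Returns the created node, or ``None``.
        """
        if record.activity == "Transfect":
            if record.sample in self._nodes:
                return None  # root pre-registered by the transfection entry
            return self.add_root(record.parsed_sample, record.seq)
        node = self.node(record.sample)
        created = None
        if new_clone_well is not None:
            clone = derive_clone_name(node.parsed, new_clone_well)
            created = self._add(clone, parent=node.name, seq=record.seq)
        if record.activity == "Sort":
            derived = derive_sort_name(node.parsed)
            created = self._add(derived, parent=node.name, seq=record.seq)
        elif record.activity == "Discontinue":
            node.status = DISCONTINUED
        return created

    # --- queries --------------------------------------------------------

    def ancestors(self, name: str) -> list[str]:
        """Chain from root transfection to ``name`` inclusive, root first."""
        chain: list[str] = []
        current: Optional[str] = self.node(name).name
        while current is not None:
            chain.append(current)
            current = self._nodes[current].parent
        chain.reverse()
        return chain

    def descendants(self, name: str) -> list[str]:
        """All samples derived (transitively) from ``name``, in creation
        order; ``name`` itself excluded."""
        self.node(name)
        out = []
        for node in self._nodes.values():
            if node.name != name and name in self.ancestors(node.name):
                out.append(node.name)
        return out

    def root_of(self, name: str) -> str:
        return self.ancestors(name)[0]

    def roots(self) -> list[str]:
        return [n.name for n in self._nodes.values() if n.parent is None]

    def list_samples(self) -> list[str]:
        """All names, most recently created first (the drop-down order)."""
        return [n.name for n in reversed(self._nodes.values())]

    def transfection_members(self, designator: str) -> list[str]:
        """Every sample in the tree rooted at ``designator``, root included,
        in creation order."""
        node = self.node(designator)
        if node.parent is not None:
            raise LookupError_(f"{designator!r} is not a transfection root")
        return [designator] + self.descendants(designator)

    def clone_level_samples(self) -> list[str]:
        """Names with a well and no sort suffix — the designated clones."""
        return [
            n.name
            for n in self._nodes.values()
            if n.parsed.well is not None and n.parsed.sort_index is None
        ]

    def lineage_discontinued(self, name: str) -> bool:
        """True when the sample or any of its derivatives was discontinued."""
        if self.node(name).status == DISCONTINUED:
            return True
        return any(
            self._nodes[d].status == DISCONTINUED for d in self.descendants(name)
        )

    def max_sort_index(self, name: str) -> int:
        """Deepest sort count reached in the subtree of ``name`` (0 when
        never sorted)."""
        indices = [self.node(name).parsed.sort_index or 0]
        indices += [
            self._nodes[d].parsed.sort_index or 0 for d in self.descendants(name)
        ]
        return max(indices)

    # --- persistence (the Cell Samples worksheet analog) ----------------

    CSV_HEADER = ("name", "parent", "created_seq", "status")

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\r\n")
        writer.writerow(self.CSV_HEADER)
        for node in self._nodes.values():
            writer.writerow(
                [node.name, node.parent or "", node.created_seq, node.status]
            )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, vocab) -> "SampleRegistry":
        reg = cls()
        reader = csv.reader(io.StringIO(text, newline=""))
        header = next(reader, None)
        if header is None or tuple(header) != cls.CSV_HEADER:
            raise LookupError_("malformed samples file: bad header")
        for row in reader:
            if not row:
                continue
            name, parent, seq, status = row
            node = SampleNode(
                name, parse_name(name, vocab), parent or None, int(seq), status
            )
            reg._nodes[name] = node
        return reg
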