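"""Directory scaffolding: the registry mirrored as nested folders.

Each sample owns one directory whose path components are exactly the
names on its ancestor chain, root-first — ``root/base/base_C6/
base_C6_Sort1`` — so the folder itself is the sample's local persistent
identifier and data landing zone. Directories are only ever created,
never moved or deleted (the workspace is an archive); discontinued
samples keep their folders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import WorkspaceIOError
from .lineage import SampleRegistry


def sample_segments(registry: SampleRegistry, name: str) -> tuple[str, ...]:
    """Separator-free path for ``name``: its ancestor chain root-first."""
    return tuple(registry.ancestors(name))


def sample_path(root: Path, registry: SampleRegistry, name: str) -> Path:
    """Absolute directory for ``name`` under ``root``; nesting depth
    equals the sample's derivation depth + 1."""
    return Path(root).joinpath(*sample_segments(registry, name))


def ensure_tree(root: Path, registry: SampleRegistry) -> list[Path]:
    """Create any missing sample directories under ``root``; returns the
    paths actually created this call. Idempotent: a second run creates
    nothing, and existing folder contents are never touched."""
    root = Path(root)
    if not root.is_dir():
        raise WorkspaceIOError(f"workspace root {root} does not exist")
    created: list[Path] = []
    for node in registry:
        path = sample_path(root, registry, node.name)
        if not path.exists():
            try:
                path.mkdir(parents=True)
            except OSError as exc:
                raise WorkspaceIOError(f"cannot create {path}: {exc}") from exc
            created.append(path)
    return created


@dataclass(frozen=True)
class AuditReport:
    """Discrepancies between the registry and the directory tree."""

    missing: tuple[str, ...]       # registered samples lacking a folder
    unregistered: tuple[str, ...]  # folders (relative) lacking a registration

    @property
    def clean(self) -> bool:
        return not self.missing and not self.unregistered


def audit(root: Path, registry: SampleRegistry) -> AuditReport:
    """Compare the tree under ``root`` with the registry.

    Reports registered samples whose folder is absent, and directories
    sitting where a sample folder would (children of the root or of a
    sample folder) that no sample claims. Deeper data directories inside
    an unclaimed folder are not descended into; files are ignored.
    """
    root = Path(root)
    expected = {sample_segments(registry, node.name) for node in registry}
    missing = tuple(
        node.name
        for node in registry
        if not sample_path(root, registry, node.name).is_dir()
    )
    unregistered: list[str] = []
    if root.is_dir():
        frontier: list[tuple[str, ...]] = [()]
        while frontier:
            rel = frontier.pop(0)
            for child in sorted(p for p in root.joinpath(*rel).iterdir() if p.is_dir()):
                child_rel = rel + (child.name,)
                if child_rel in expected:
                    frontier.append(child_rel)
                else:
                    unregistered.append("/".join(child_rel))
    return AuditReport(missing, tuple(unregistered))
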