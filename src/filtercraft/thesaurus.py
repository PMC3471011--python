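"""Controlled-vocabulary trees (MeSH-like / Emtree-like) with explosion.

Descriptors carry one or more dot-separated tree numbers; "exploding" a
descriptor expands a search to the descriptor plus every descriptor whose tree
number extends one of its tree numbers — e.g. exploding a glomerulonephritis
heading automatically pulls in its histologic subtypes (IgA nephropathy,
membranous, membranoproliferative, anti-GBM disease, focal segmental
glomerulosclerosis, lupus nephritis).

The same structure serves MeSH-like and Emtree-like vocabularies; the package
ships toy versions of both covering every descriptor used by the published
glomerular-disease filters (real MeSH/Emtree are licensed and large).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class Descriptor:
    name: str
    tree_numbers: tuple[str, ...]
    entry_terms: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "tree_numbers", tuple(self.tree_numbers))
        object.__setattr__(self, "entry_terms", tuple(self.entry_terms))
        if not self.tree_numbers:
            raise ValueError(f"descriptor {self.name!r} has no tree numbers")


def normalize_name(name: str) -> str:
    """Case-insensitive key: strip quotes, collapse whitespace."""
    return " ".join(name.strip().strip('"').split()).lower()


def _inverted_forms(key: str):
    # "lupus erythematosus, systemic" is also findable as
    # "systemic lupus erythematosus" (comma-inversion convention).
    if "," in key:
        head, _, tail = key.partition(",")
        yield f"{tail.strip()} {head.strip()}"


class Thesaurus:
    """Descriptors indexed by normalized name and by entry term."""

    def __init__(self, descriptors, vocabulary_id: str = "toy"):
        self.vocabulary_id = vocabulary_id
        self.descriptors: dict[str, Descriptor] = {}
        self._index: dict[str, Descriptor] = {}
        seen_tree: dict[str, str] = {}
        for d in descriptors:
            if d.name in self.descriptors:
                raise ValueError(f"duplicate descriptor name {d.name!r}")
            for tn in d.tree_numbers:
                if tn in seen_tree:
                    raise ValueError(
                        f"tree number {tn} on both {seen_tree[tn]!r} and {d.name!r}"
                    )
                seen_tree[tn] = d.name
            self.descriptors[d.name] = d
        for d in self.descriptors.values():
            for alias in (d.name, *d.entry_terms):
                key = normalize_name(alias)
                self._register(key, d)
                for inv in _inverted_forms(key):
                    self._register(inv, d)

    def _register(self, key: str, d: Descriptor):
        prev = self._index.get(key)
        if prev is not None and prev is not d:
            # Canonical names win over entry-term aliases on collision.
            if normalize_name(prev.name) == key:
                return
        self._index[key] = d

    def __len__(self):
        return len(self.descriptors)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._index

    def lookup(self, name: str) -> Descriptor:
        key = normalize_name(name)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"descriptor {name!r} not found in vocabulary "
                f"{self.vocabulary_id!r}"
            ) from None

    def descendants(self, name: str) -> set[str]:
        """The descriptor plus every descriptor any of whose tree numbers
        extends one of its tree numbers by >= 1 dot segment (explosion)."""
        d = self.lookup(name)
        prefixes = tuple(tn + "." for tn in d.tree_numbers)
        out = {d.name}
        for other in self.descriptors.values():
            for tn in other.tree_numbers:
                if tn.startswith(prefixes):
                    out.add(other.name)
                    break
        return out


def descendants(thesaurus: Thesaurus, name: str) -> set[str]:
    return thesaurus.descendants(name)


# ---------------------------------------------------------------------------
# I/O


def _from_json_obj(obj: dict) -> Thesaurus:
    descs = [
        Descriptor(
            name=d["name"],
            tree_numbers=tuple(d["tree_numbers"]),
            entry_terms=tuple(d.get("entry_terms", ())),
        )
        for d in obj["descriptors"]
    ]
    return Thesaurus(descs, vocabulary_id=obj.get("vocabulary_id", "unnamed"))


def load_thesaurus(path) -> Thesaurus:
    """Load a thesaurus from JSON ({vocabulary_id, descriptors:[...]}) or TSV
    (name <tab> ;-joined tree numbers <tab> ;-joined entry terms)."""
    text = open(path, encoding="utf-8").read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return _from_json_obj(json.loads(text))
    descs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected >=2 tab fields")
        name = parts[0].strip()
        tree = tuple(t.strip() for t in parts[1].split(";") if t.strip())
        entries = ()
        if len(parts) > 2:
            entries = tuple(t.strip() for t in parts[2].split(";") if t.strip())
        descs.append(Descriptor(name, tree, entries))
    return Thesaurus(descs, vocabulary_id=str(path))


def _load_builtin(filename: str, vocab_id: str) -> Thesaurus:
    data = resources.files("filtercraft.data").joinpath(filename).read_text("utf-8")
    obj = json.loads(data)
    obj.setdefault("vocabulary_id", vocab_id)
    return _from_json_obj(obj)


def toy_mesh() -> Thesaurus:
    """Bundled MeSH-like toy vocabulary (kidney-disease subtree and friends)."""
    return _load_builtin("toy_mesh.json", "toy_mesh")


def toy_emtree() -> Thesaurus:
    """Bundled Emtree-like toy vocabulary for the Embase-dialect filters."""
    return _load_builtin("toy_emtree.json", "toy_emtree")


def default_thesaurus_for(dialect: str) -> Thesaurus:
    return toy_emtree() if dialect == "ovid_embase" else toy_mesh()
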