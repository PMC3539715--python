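"""Fixed eight-mammal phylogeny with Ks branch lengths and branch roles.

The analyses in this package run on a single, fixed rooted topology::

    ((((human,chimpanzee),macaque),(mouse,rat)),((horse,dog),cow));

i.e. Euarchontoglires (primates + rodents) versus Laurasiatheria
(horse, dog, cow), rooted on the branch separating the two clades.
Branch lengths are mean synonymous divergences (Ks, substitutions per
synonymous site), which serve as a near-neutral clock.

The unrooted tree has thirteen branches: eight terminal branches plus
the stems of the human-chimp, primate, mouse-rat and horse-dog clades
and the single central branch separating the two superorders.  The
central branch is labelled ``"root"``; because the underlying codon
models produce unrooted trees, the Ks assigned to the two root-adjacent
rooted edges cannot be distinguished and each is taken as one half of
the central separation.

Five *origin-eligible* branch classes lie on the path from the root to
the human tip (oldest to youngest): ``root`` (appearance at or before
the root), ``euarchontoglires``, ``primates``, ``human-chimp`` and
``human``.  Two internal branches off the human lineage, the mouse-rat
and horse-dog stems, are *loss-calibration* branches used to estimate
rates of interaction loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import yaml

SPECIES: tuple[str, ...] = (
    "human",
    "chimpanzee",
    "macaque",
    "mouse",
    "rat",
    "horse",
    "dog",
    "cow",
)

REFERENCE_SPECIES = "human"

#: Canonical branch labels of the unrooted 13-branch tree, in the fixed
#: order used to align mirrortree vectors.
BRANCHES: tuple[str, ...] = SPECIES + (
    "human-chimp",
    "primates",
    "mouse-rat",
    "horse-dog",
    "root",
)

#: Tip set on the far-from-human side of each branch.
BRANCH_CLADES: dict[str, frozenset[str]] = {
    "human": frozenset({"human"}),
    "chimpanzee": frozenset({"chimpanzee"}),
    "macaque": frozenset({"macaque"}),
    "mouse": frozenset({"mouse"}),
    "rat": frozenset({"rat"}),
    "horse": frozenset({"horse"}),
    "dog": frozenset({"dog"}),
    "cow": frozenset({"cow"}),
    "human-chimp": frozenset({"human", "chimpanzee"}),
    "primates": frozenset({"human", "chimpanzee", "macaque"}),
    "mouse-rat": frozenset({"mouse", "rat"}),
    "horse-dog": frozenset({"horse", "dog"}),
    "root": frozenset({"horse", "dog", "cow"}),
}

#: Origin-eligible branch classes, ordered oldest (root) to youngest.
ORIGIN_CLASSES: tuple[str, ...] = (
    "root",
    "euarchontoglires",
    "primates",
    "human-chimp",
    "human",
)

#: Species below (i.e. potentially carrying a gene that appeared on)
#: each origin-eligible branch class.
CLASS_CLADES: dict[str, frozenset[str]] = {
    "root": frozenset(SPECIES),
    "euarchontoglires": frozenset({"human", "chimpanzee", "macaque", "mouse", "rat"}),
    "primates": frozenset({"human", "chimpanzee", "macaque"}),
    "human-chimp": frozenset({"human", "chimpanzee"}),
    "human": frozenset({"human"}),
}

LOSS_CALIBRATION_BRANCHES: tuple[str, ...] = ("mouse-rat", "horse-dog")

#: Origin-class index a pair must have (at most) for both orthologs to be
#: inferred present at the calibration branch's parent node.
CALIBRATION_PARENT_CLASS: dict[str, str] = {
    "mouse-rat": "euarchontoglires",  # parent = euarchontoglires ancestor
    "horse-dog": "root",  # parent = laurasiatheria ancestor
}

CALIBRATION_TIPS: dict[str, tuple[str, str]] = {
    "mouse-rat": ("mouse", "rat"),
    "horse-dog": ("horse", "dog"),
}


class PhylogenyError(ValueError):
    """Invalid tree, branch length or role configuration."""


@dataclass(frozen=True)
class Phylogeny:
    """The fixed 8-taxon topology plus per-branch Ks and branch roles.

    Parameters
    ----------
    branch_ks
        Mapping from the 13 canonical branch labels to mean Ks.  The
        ``"root"`` entry is the *full* Ks separation between the
        rodent-primate and horse-dog-cow clades; class-level lookups
        halve it.
    """

    branch_ks: Mapping[str, float]
    origin_classes: tuple[str, ...] = ORIGIN_CLASSES
    loss_calibration: tuple[str, ...] = LOSS_CALIBRATION_BRANCHES

    def __post_init__(self) -> None:
        missing = set(BRANCHES) - set(self.branch_ks)
        if missing:
            raise PhylogenyError(f"missing Ks for branches: {sorted(missing)}")
        extra = set(self.branch_ks) - set(BRANCHES)
        if extra:
            raise PhylogenyError(f"unknown branch labels: {sorted(extra)}")
        for label, ks in self.branch_ks.items():
            if not ks >= 0:
                raise PhylogenyError(f"negative Ks on branch {label!r}: {ks}")
        if tuple(self.origin_classes) != ORIGIN_CLASSES:
            raise PhylogenyError(
                "origin-eligible classes must be the five human-lineage "
                f"classes in order {ORIGIN_CLASSES}"
            )
        if set(self.loss_calibration) != set(LOSS_CALIBRATION_BRANCHES):
            raise PhylogenyError(
                f"loss-calibration branches must be {LOSS_CALIBRATION_BRANCHES}"
            )

    # -- basic lookups -------------------------------------------------
    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES

    @property
    def central_ks(self) -> float:
        """Full Ks separation between the two superorders."""
        return float(self.branch_ks["root"])

    def class_index(self, origin_class: str) -> int:
        """0 for the root class, 4 for the human-terminal class."""
        try:
            return ORIGIN_CLASSES.index(origin_class)
        except ValueError:
            raise PhylogenyError(f"unknown origin class {origin_class!r}") from None

    def class_clade(self, origin_class: str) -> frozenset[str]:
        self.class_index(origin_class)
        return CLASS_CLADES[origin_class]

    def class_ks(self, origin_class: str) -> float:
        """Ks length of an origin-eligible branch class.

        The root and euarchontoglires-stem classes both live on the
        central branch, whose rooted halves cannot be distinguished;
        each gets half the central separation.
        """
        self.class_index(origin_class)
        if origin_class in ("root", "euarchontoglires"):
            return self.central_ks / 2.0
        return float(self.branch_ks[origin_class])

    def class_age(self, origin_class: str) -> float:
        """Ks distance from the human tip to the midpoint of the class branch."""
        idx = self.class_index(origin_class)
        # cumulative Ks of the younger class branches, youngest first
        path = [self.class_ks(c) for c in ORIGIN_CLASSES]
        below = sum(path[idx + 1 :])
        return below + path[idx] / 2.0

    def younger_class(self, class_a: str, class_b: str) -> str:
        """The more recent (closer to human) of two origin classes."""
        return max(class_a, class_b, key=self.class_index)

    def mrca_origin_class(self, present: Iterable[str]) -> str:
        """Origin class of the branch immediately ancestral to the MRCA
        of a set of species carrying an ortholog.

        The set must contain human (genes are defined from the human
        gene set).  An MRCA at or above the euarchontoglires /
        laurasiatheria split maps to the root class.
        """
        present = frozenset(present)
        unknown = present - set(SPECIES)
        if unknown:
            raise PhylogenyError(f"unknown species: {sorted(unknown)}")
        if REFERENCE_SPECIES not in present:
            raise PhylogenyError("presence set must include human")
        # youngest class whose clade contains every present species
        for origin_class in reversed(ORIGIN_CLASSES):
            if present <= CLASS_CLADES[origin_class]:
                return origin_class
        return "root"  # unreachable: root clade is all species


# ---------------------------------------------------------------------------
# Newick + role-configuration I/O
# ---------------------------------------------------------------------------

#: Role file shipped alongside every fixture; kept in config rather than
#: hard-coded Newick comments because branch identities are a modelling
#: choice, not part of the Newick format.
DEFAULT_ROLES: dict = {
    "origin_eligible": list(ORIGIN_CLASSES),
    "loss_calibration": list(LOSS_CALIBRATION_BRANCHES),
}

# leaf sets identifying internal edges of the rooted tree
_INTERNAL_BY_LEAFSET = {
    frozenset({"human", "chimpanzee"}): "human-chimp",
    frozenset({"human", "chimpanzee", "macaque"}): "primates",
    frozenset({"mouse", "rat"}): "mouse-rat",
    frozenset({"horse", "dog"}): "horse-dog",
}
_EUARCH = frozenset({"human", "chimpanzee", "macaque", "mouse", "rat"})
_LAUR = frozenset({"horse", "dog", "cow"})


def read_roles(path) -> dict:
    """Read and validate the branch-role configuration (YAML)."""
    with open(path) as fh:
        roles = yaml.safe_load(fh)
    if not isinstance(roles, dict):
        raise PhylogenyError(f"{path}: role file must be a mapping")
    got = tuple(roles.get("origin_eligible", ()))
    if got != ORIGIN_CLASSES:
        raise PhylogenyError(
            f"{path}: origin_eligible must list {ORIGIN_CLASSES} in order, got {got}"
        )
    if set(roles.get("loss_calibration", ())) != set(LOSS_CALIBRATION_BRANCHES):
        raise PhylogenyError(
            f"{path}: loss_calibration must name {LOSS_CALIBRATION_BRANCHES}"
        )
    return {"origin_eligible": list(got), "loss_calibration": list(roles["loss_calibration"])}


def write_roles(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_ROLES, fh, sort_keys=False)


def read_phylogeny(newick_path, roles_path=None) -> Phylogeny:
    """Read the 8-taxon tree (branch lengths = Ks) from a Newick file.

    The two root-adjacent edges are summed into the single central
    ``"root"`` branch; an unrooted (trifurcating) input where the
    horse-dog-cow clade hangs off a single basal edge is handled the
    same way.  A role configuration, when given, is validated against
    the fixed class structure.
    """
    if roles_path is not None:
        read_roles(roles_path)
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    tips = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
    expected = set(SPECIES)
    if tips != expected:
        missing = expected - tips
        extra = tips - expected
        raise PhylogenyError(
            f"tree tips do not match the 8 required species; "
            f"missing={sorted(missing)} unexpected={sorted(extra)}"
        )
    ks: dict[str, float] = {}
    central = 0.0
    for node in tree.preorder_node_iter():
        edge = node.edge
        if edge.tail_node is None:
            continue  # root has no branch
        length = edge.length if edge.length is not None else 0.0
        if length < 0:
            raise PhylogenyError(f"negative branch length {length}")
        if node.is_leaf():
            ks[node.taxon.label.replace(" ", "_")] = float(length)
            continue
        leafset = frozenset(
            leaf.taxon.label.replace(" ", "_") for leaf in node.leaf_iter()
        )
        if leafset in _INTERNAL_BY_LEAFSET:
            ks[_INTERNAL_BY_LEAFSET[leafset]] = float(length)
        elif leafset in (_EUARCH, _LAUR):
            central += float(length)
        else:
            raise PhylogenyError(f"unexpected internal clade {sorted(leafset)}")
    ks["root"] = central
    missing = set(BRANCHES) - set(ks)
    if missing:
        raise PhylogenyError(f"tree is missing branches: {sorted(missing)}")
    return Phylogeny(branch_ks=ks)


def to_newick(phylo: Phylogeny) -> str:
    """Rooted Newick string; the central Ks is split evenly across the
    two root-adjacent edges (they are indistinguishable under the
    unrooted models that produced the lengths)."""
    ks = phylo.branch_ks
    half = phylo.central_ks / 2.0

    def f(x: float) -> str:
        return format(x, ".10g")

    return (
        "(((("
        f"human:{f(ks['human'])},chimpanzee:{f(ks['chimpanzee'])})"
        f":{f(ks['human-chimp'])},macaque:{f(ks['macaque'])})"
        f":{f(ks['primates'])},(mouse:{f(ks['mouse'])},rat:{f(ks['rat'])})"
        f":{f(ks['mouse-rat'])}):{f(half)},"
        f"((horse:{f(ks['horse'])},dog:{f(ks['dog'])}):{f(ks['horse-dog'])},"
        f"cow:{f(ks['cow'])}):{f(half)});\n"
    )


def write_phylogeny(phylo: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(phylo))
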