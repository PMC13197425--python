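"""Small-pedigree representation, consistency checking and enumeration.

Ancient-DNA kinship software reports pairwise relatedness *degrees*
(1st: parent-offspring or full siblings; 2nd: half-siblings,
grandparent-grandchild, avuncular; 3rd: first cousins,
great-grandparent-great-grandchild, half-avuncular) but not the
genealogy itself.  This module turns observed degrees, mitochondrial
haplotypes and sexes into explicit family trees:

* :func:`check_pedigree_consistency` verifies a proposed tree against
  the observations,
* :func:`enumerate_pedigrees` exhaustively lists every consistent tree
  over a handful of sampled individuals plus a bounded number of
  unsampled placeholders, and
* :func:`pedigree_to_constraints` converts parent-child edges into
  generational-gap priors for the chronological model (mothers are
  24 +/- 6 years old at a child's birth, fathers 28 +/- 7).

Degrees are mapped from the kinship coefficient computed on the tree;
inbreeding-inflated degrees are out of scope.  Unknown mitochondrial
haplotypes match anything (conservative).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "MATERNAL_GAP",
    "PATERNAL_GAP",
    "PedigreeIndividual",
    "RelationEdge",
    "FamilyTree",
    "GenerationGap",
    "PedigreeError",
    "SearchOverflowError",
    "check_pedigree_consistency",
    "enumerate_pedigrees",
    "pedigree_to_constraints",
]

#: mean and sd (years) of a mother's age at any child's birth
MATERNAL_GAP = (24.0, 6.0)
#: mean and sd (years) of a father's age at any child's birth
PATERNAL_GAP = (28.0, 7.0)


class PedigreeError(ValueError):
    """Structural pedigree problem (cycle, double mother, sex conflict)."""


class SearchOverflowError(RuntimeError):
    """Pedigree enumeration exceeded its node budget; tighten the bounds."""


@dataclass(frozen=True)
class PedigreeIndividual:
    id: str
    sex: str = "unknown"  # female | male | unknown
    mt_haplotype: str | None = None
    sampled: bool = True
    age_at_death: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"sex must be female|male|unknown, got {self.sex!r}")
        if self.age_at_death is not None and self.age_at_death[0] > self.age_at_death[1]:
            raise ValueError(f"{self.id}: age_at_death min > max")


@dataclass(frozen=True)
class RelationEdge:
    """Observed pairwise relatedness degree (unordered pair)."""

    a: str
    b: str
    degree: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-relations are not allowed")
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


class FamilyTree:
    """Directed parent -> child structure with mother/father roles.

    ``parents[child] = {"mother": id or None, "father": id or None}``.
    May include unsampled placeholder individuals.
    """

    def __init__(self) -> None:
        self.parents: dict[str, dict[str, str | None]] = {}

    def add_individual(self, ind_id: str) -> None:
        self.parents.setdefault(ind_id, {"mother": None, "father": None})

    def set_parent(self, child: str, parent: str, role: str) -> None:
        if role not in ("mother", "father"):
            raise ValueError(f"role must be mother|father, got {role!r}")
        self.add_individual(child)
        self.add_individual(parent)
        existing = self.parents[child][role]
        if existing is not None and existing != parent:
            raise PedigreeError(f"{child} already has a {role} ({existing})")
        self.parents[child][role] = parent
        if self._has_cycle():
            self.parents[child][role] = existing
            raise PedigreeError(f"edge {parent} -> {child} would create a cycle")

    # -- structure ----------------------------------------------------------

    def individuals(self) -> list[str]:
        return sorted(self.parents)

    def parent_edges(self) -> list[tuple[str, str, str]]:
        """Sorted list of (child, parent, role)."""
        out = []
        for child in sorted(self.parents):
            for role in ("mother", "father"):
                p = self.parents[child][role]
                if p is not None:
                    out.append((child, p, role))
        return out

    def children_of(self, ind_id: str) -> list[str]:
        return sorted(
            c for c, slots in self.parents.items() if ind_id in slots.values()
        )

    def _has_cycle(self) -> bool:
        color: dict[str, int] = {}

        def visit(node: str) -> bool:
            color[node] = 1
            for p in self.parents.get(node, {}).values():
                if p is None:
                    continue
                c = color.get(p, 0)
                if c == 1 or (c == 0 and visit(p)):
                    return True
            color[node] = 2
            return False

        return any(color.get(n, 0) == 0 and visit(n) for n in list(self.parents))

    def ancestors(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            node = stack.pop()
            for p in self.parents.get(node, {}).values():
                if p is not None and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    # -- relatedness --------------------------------------------------------

    def kinship(self, a: str, b: str, _memo: dict | None = None) -> float:
        """Kinship coefficient phi on the tree (missing parents are
        treated as unrelated founders)."""
        memo = _memo if _memo is not None else {}

        def phi(x: str, y: str) -> float:
            key = (x, y) if x <= y else (y, x)
            if key in memo:
                return memo[key]
            if x == y:
                fx = self.parents.get(x, {})
                m, f = fx.get("mother"), fx.get("father")
                val = 0.5 * (1.0 + (phi(m, f) if m and f else 0.0))
            else:
                # recurse on the one that is not an ancestor of the other
                if x in self.ancestors(y):
                    target, other = y, x
                elif y in self.ancestors(x):
                    target, other = x, y
                else:
                    target, other = x, y  # neither ancestral: either works
                slots = self.parents.get(target, {})
                m, f = slots.get("mother"), slots.get("father")
                val = 0.5 * (
                    (phi(other, m) if m else 0.0) + (phi(other, f) if f else 0.0)
                )
            memo[key] = val
            return val

        return phi(a, b)

    def implied_degree(self, a: str, b: str) -> int | None:
        """Relatedness degree implied by the tree, or None if unrelated,
        more distant than 3rd degree, or outside the standard classes.

        Only the exact non-inbred kinship values map to a class
        (phi = 1/4 -> 1st, 1/8 -> 2nd, 1/16 -> 3rd); inbreeding-inflated
        coefficients are deliberately not classified."""
        phi = self.kinship(a, b)
        for d, v in ((1, 0.25), (2, 0.125), (3, 0.0625)):
            if abs(phi - v) < 1e-9:
                return d
        return None

    # -- maternal lineages --------------------------------------------------

    def maternal_components(self) -> dict[str, str]:
        """Map each individual to a maternal-lineage component label
        (individuals in one component share a mitochondrial lineage)."""
        root: dict[str, str] = {}

        def find(x: str) -> str:
            while root.setdefault(x, x) != x:
                root[x] = root[root[x]]
                x = root[x]
            return x

        for child, slots in self.parents.items():
            m = slots.get("mother")
            if m is not None:
                root[find(child)] = find(m)
        return {x: find(x) for x in self.parents}

    def copy(self) -> "FamilyTree":
        t = FamilyTree()
        t.parents = {c: dict(s) for c, s in self.parents.items()}
        return t

    def __eq__(self, other) -> bool:
        return isinstance(other, FamilyTree) and self.parent_edges() == other.parent_edges() \
            and set(self.parents) == set(other.parents)

    def __repr__(self) -> str:
        edges = ", ".join(f"{p}-[{r}]->{c}" for c, p, r in self.parent_edges())
        return f"FamilyTree({edges or 'no edges'})"


@dataclass(frozen=True)
class GenerationGap:
    """Prior on a child's birth year relative to a parent's:
    ``child_birth = parent_birth + Normal(mean, sd)`` (years)."""

    parent: str
    child: str
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# consistency


def check_pedigree_consistency(
    tree: FamilyTree,
    edges: Sequence[RelationEdge],
    individuals: Sequence[PedigreeIndividual],
    require_complete: bool = False,
) -> list[str]:
    """Return the list of violations (empty list means consistent).

    Checks, in order: structural sanity (acyclicity is enforced at
    construction; here sex-role agreement), tree-implied degree versus
    every observed :class:`RelationEdge`, and mitochondrial-haplotype
    agreement along maternal lineages (untyped individuals match
    anything).  With ``require_complete=True``, sampled pairs *without*
    an observed edge must be unrelated (no implied degree <= 3) — the
    setting used during enumeration.
    """
    if tree._has_cycle():
        raise PedigreeError("tree contains a cycle")
    by_id = {i.id: i for i in individuals}
    violations: list[str] = []

    for child, parent, role in tree.parent_edges():
        sex = by_id[parent].sex if parent in by_id else "unknown"
        want = "female" if role == "mother" else "male"
        if sex not in (want, "unknown"):
            violations.append(f"{parent} is {sex} but is the {role} of {child}")

    for e in edges:
        got = tree.implied_degree(e.a, e.b)
        if got != e.degree:
            violations.append(
                f"observed degree {e.degree} for ({e.a}, {e.b}) but tree implies "
                f"{got if got is not None else 'unrelated'}"
            )
    if require_complete:
        observed = {e.pair for e in edges}
        sampled = [i.id for i in individuals if i.sampled and i.id in tree.parents]
        for a, b in itertools.combinations(sorted(sampled), 2):
            if frozenset((a, b)) not in observed:
                got = tree.implied_degree(a, b)
                if got is not None:
                    violations.append(
                        f"tree implies degree {got} for unobserved pair ({a}, {b})"
                    )

    # mitochondrial lineages: all typed members of one maternal component
    # must carry the same haplotype
    comp = tree.maternal_components()
    seen: dict[str, tuple[str, str]] = {}
    for ind_id in sorted(tree.parents):
        hap = by_id[ind_id].mt_haplotype if ind_id in by_id else None
        if hap is None:
            continue
        c = comp[ind_id]
        if c in seen and seen[c][1] != hap:
            violations.append(
                f"mt haplotype mismatch on a maternal lineage: {seen[c][0]}={seen[c][1]} "
                f"vs {ind_id}={hap}"
            )
        else:
            seen.setdefault(c, (ind_id, hap))
    return violations


# ---------------------------------------------------------------------------
# enumeration


def _degree_bound_violated(
    tree: FamilyTree, sampled_ids: Sequence[str], allowed: dict[frozenset, int]
) -> bool:
    """True if the partial tree already relates some sampled pair more
    closely than the observations permit.  Kinship only grows as edges
    are added, so this is a sound prune."""
    for a, b in itertools.combinations(sampled_ids, 2):
        phi = tree.kinship(a, b)
        if phi <= 0.0:
            continue
        deg = allowed.get(frozenset((a, b)))
        max_phi = 0.25 * 0.5 ** (deg - 1) if deg else 0.5**4  # unobserved: < 4th
        if phi > max_phi + 1e-12:
            return True
    return False


def _mt_violated(tree: FamilyTree, by_id: dict[str, PedigreeIndividual]) -> bool:
    comp = tree.maternal_components()
    seen: dict[str, str] = {}
    for ind_id in tree.parents:
        ind = by_id.get(ind_id)
        hap = ind.mt_haplotype if ind else None
        if hap is None:
            continue
        c = comp[ind_id]
        if seen.setdefault(c, hap) != hap:
            return True
    return False


def _canonical_signature(tree: FamilyTree, unsampled: Sequence[str], sexes: dict[str, str]):
    """Tree signature invariant under relabeling of unsampled placeholders."""
    best = None
    for perm in itertools.permutations(range(len(unsampled))):
        relab = {u: f"?{perm[i]}" for i, u in enumerate(unsampled)}
        edges = tuple(
            sorted(
                (relab.get(c, c), relab.get(p, p), r)
                for c, p, r in tree.parent_edges()
            )
        )
        sx = tuple(sorted((relab[u], sexes.get(u, "unknown")) for u in unsampled))
        sig = (edges, sx)
        if best is None or sig < best:
            best = sig
    return best


def enumerate_pedigrees(
    individuals: Sequence[PedigreeIndividual],
    edges: Sequence[RelationEdge],
    max_unsampled: int = 2,
    node_budget: int = 3_000_000,
) -> list[FamilyTree]:
    """Exhaustively enumerate family trees consistent with the observed
    degrees, sexes and mitochondrial haplotypes.

    Trees may contain up to ``max_unsampled`` placeholder individuals
    (ids ``"?0"``, ``"?1"``, ...) whose sexes are inferred from the
    parental roles they take.  Every placeholder must be load-bearing
    (at least one child, and either two children or a parent), which
    also deduplicates trees that differ only by pendant ancestors.
    Output is deduplicated up to relabeling of the placeholders and
    deterministically ordered.

    Raises :class:`SearchOverflowError` when the search exceeds
    ``node_budget`` expansions.
    """
    sampled = [i for i in individuals if i.sampled]
    if len(sampled) > 6:
        raise ValueError("enumeration supports at most 6 sampled individuals")
    if max_unsampled > 4:
        raise ValueError("enumeration supports at most 4 unsampled placeholders")
    ids = {i.id for i in individuals}
    for e in edges:
        if not e.pair <= ids:
            raise ValueError(f"relation references unknown individual: {e}")

    by_id = {i.id: i for i in individuals}
    sampled_ids = [i.id for i in sampled]
    allowed = {e.pair: e.degree for e in edges}
    unsampled_pool = [f"?{j}" for j in range(max_unsampled)]

    results: list[FamilyTree] = []
    seen_sigs: set = set()
    counter = {"nodes": 0}

    def run(order: tuple[str, ...], tree: FamilyTree, sexes: dict[str, str], used: list[str], idx: int):
        counter["nodes"] += 1
        if counter["nodes"] > node_budget:
            raise SearchOverflowError(
                f"pedigree search exceeded {node_budget} nodes; reduce max_unsampled "
                f"or the number of individuals"
            )
        if idx == len(order):
            finalize(tree, sexes, used)
            return
        child = order[idx]

        def candidates(want: str, used_now: list[str]) -> list[str | None]:
            # everyone placed so far plus (canonically) the next fresh placeholder
            opts: list[str | None] = [None]
            pool = sampled_ids + used_now + (
                [unsampled_pool[len(used_now)]] if len(used_now) < max_unsampled else []
            )
            for cand in pool:
                if cand == child:
                    continue
                sex = sexes.get(cand, by_id[cand].sex if cand in by_id else "unknown")
                if sex in (want, "unknown"):
                    opts.append(cand)
            return opts

        for mother in candidates("female", used):
            u_mid = used + [mother] if (
                mother is not None and mother.startswith("?") and mother not in used
            ) else used
            for father in candidates("male", u_mid):
                if mother is not None and mother == father:
                    continue
                t = tree.copy()
                sx = dict(sexes)
                u = list(used)
                new_order = list(order)
                ok = True
                for parent, role, want in (
                    (mother, "mother", "female"),
                    (father, "father", "male"),
                ):
                    if parent is None:
                        continue
                    cur = sx.get(parent, by_id[parent].sex if parent in by_id else "unknown")
                    if cur not in (want, "unknown"):
                        ok = False
                        break
                    try:
                        t.set_parent(child, parent, role)
                    except PedigreeError:
                        ok = False
                        break
                    sx[parent] = want
                    if parent.startswith("?") and parent not in u:
                        u.append(parent)
                        new_order.append(parent)
                if not ok:
                    continue
                # co-parents must be unrelated: inbred offspring are out of scope
                if mother is not None and father is not None and t.kinship(mother, father) > 0:
                    continue
                if _degree_bound_violated(t, sampled_ids, allowed) or _mt_violated(t, by_id):
                    continue
                run(tuple(new_order), t, sx, u, idx + 1)

    def finalize(tree: FamilyTree, sexes: dict[str, str], used: list[str]):
        t = tree.copy()
        for sid in sampled_ids:
            t.add_individual(sid)
        # placeholders must be load-bearing
        for u in used:
            kids = t.children_of(u)
            has_parent = any(v is not None for v in t.parents.get(u, {}).values())
            if len(kids) == 0 or (len(kids) < 2 and not has_parent):
                return
        # no inbred offspring anywhere in the accepted tree
        for child, slots in t.parents.items():
            m, f = slots.get("mother"), slots.get("father")
            if m and f and t.kinship(m, f) > 0:
                return
        pseudo = [
            PedigreeIndividual(u, sex=sexes.get(u, "unknown"), sampled=False)
            for u in used
        ]
        if check_pedigree_consistency(
            t, edges, list(individuals) + pseudo, require_complete=True
        ):
            return
        sig = _canonical_signature(t, used, sexes)
        if sig in seen_sigs:
            return
        seen_sigs.add(sig)
        results.append(t)

    base = FamilyTree()
    for sid in sampled_ids:
        base.add_individual(sid)
    run(tuple(sampled_ids), base, {}, [], 0)
    results.sort(key=lambda t: tuple(t.parent_edges()))
    return results


# ---------------------------------------------------------------------------
# constraints


def pedigree_to_constraints(
    tree: FamilyTree,
    maternal: tuple[float, float] = MATERNAL_GAP,
    paternal: tuple[float, float] = PATERNAL_GAP,
) -> list[GenerationGap]:
    """One generational-gap prior per parent edge; chains through
    intermediate (possibly unsampled) individuals compose additively in
    the chronological model because the gaps are independent normals."""
    out = []
    for child, parent, role in tree.parent_edges():
        mean, sd = maternal if role == "mother" else paternal
        out.append(GenerationGap(parent=parent, child=child, mean=mean, sd=sd))
    return out
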