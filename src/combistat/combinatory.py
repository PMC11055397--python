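"""Enumeration of every valid pairwise comparison over a set of condition
classes.

Comparisons are generated in two stages.  Stage one compares each class
individually against every other class: C(n, 2) single-class pairs.  Stage
two enumerates every two-block set partition {T1, T2} of the class set S —
blocks disjoint, non-empty, and jointly covering S — and compares the pooled
blocks, excluding the superset partition {S}, the all-singletons partition,
and any bipartition already produced by stage one (the singleton-vs-singleton
bipartition that exists only when n = 2).  A "contrast others" mode compares
one class of interest against all remaining classes pooled and labelled
"Others".
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .core_data import ClassSet, CombistatError

DEFAULT_PLAN_CAP = 1000


@dataclass(frozen=True)
class Comparison:
    """Two disjoint, non-empty sets of class labels to contrast.

    ``group_a`` and ``group_b`` are stored lexicographically sorted; the two
    groups are ordered so the name is deterministic.  ``b_label`` overrides
    the display label of group_b (used for "Others" pooling).
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    b_label: str | None = None

    def __post_init__(self):
        a = tuple(sorted(set(self.group_a)))
        b = tuple(sorted(set(self.group_b)))
        if not a or not b:
            raise CombistatError("comparison groups must be non-empty")
        if set(a) & set(b):
            raise CombistatError(
                f"comparison groups overlap: {sorted(set(a) & set(b))}")
        # deterministic group order: smaller group first (the "class of
        # interest" side), ties broken lexicographically
        if self.b_label is None and (len(b), b) < (len(a), a):
            a, b = b, a
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)

    @property
    def name(self) -> str:
        a = "+".join(self.group_a)
        b = self.b_label if self.b_label is not None else "+".join(self.group_b)
        return f"{a}_vs_{b}"

    def key(self) -> frozenset:
        """Unordered identity: {group_a} vs {group_b} equals the swap."""
        return frozenset((self.group_a, self.group_b))


@dataclass
class ComparisonPlan:
    comparisons: list[Comparison]
    class_set: ClassSet

    def __post_init__(self):
        seen = set()
        for c in self.comparisons:
            if c.key() in seen:
                raise CombistatError(f"duplicate comparison {c.name}")
            seen.add(c.key())
            unknown = (set(c.group_a) | set(c.group_b)) - set(self.class_set.classes)
            if unknown:
                raise CombistatError(f"comparison {c.name} uses unknown classes "
                                     f"{sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.comparisons)

    def __iter__(self):
        return iter(self.comparisons)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.comparisons]


def _require_classes(class_set: ClassSet) -> None:
    if class_set.n < 2:
        raise CombistatError("need >=2 classes to form comparisons")


def enumerate_single_pairs(class_set: ClassSet) -> ComparisonPlan:
    """All C(n, 2) comparisons of one class against another."""
    _require_classes(class_set)
    comps = [Comparison((a,), (b,))
             for a, b in combinations(class_set.classes, 2)]
    return ComparisonPlan(comps, class_set)


def enumerate_grouped_pairs(class_set: ClassSet) -> ComparisonPlan:
    """All two-block covering partitions of the class set, pooled per block.

    Every bipartition {T1, T2} with T1 ∪ T2 = S, T1 ∩ T2 = ∅ and both blocks
    non-empty is emitted, except those already covered by the single-class
    stage (both blocks singletons, which happens only for n = 2).  Blocks of
    size |S|−1 against a singleton are allowed; the superset {S} and the
    partition of S into n singletons are never two-block partitions and so
    never appear.
    """
    _require_classes(class_set)
    labels = class_set.classes
    n = class_set.n
    anchor = labels[0]
    comps = []
    rest = labels[1:]
    # enumerate bipartitions once by fixing the anchor class in block A
    for r in range(0, n):
        for subset in combinations(rest, r):
            block_a = tuple(sorted((anchor,) + subset))
            block_b = tuple(sorted(set(labels) - set(block_a)))
            if not block_b:
                continue                      # the superset partition
            if len(block_a) == 1 and len(block_b) == 1:
                continue                      # already a single-class pair
            comps.append(Comparison(block_a, block_b))
    comps.sort(key=lambda c: (len(c.group_a) + len(c.group_b), c.name))
    return ComparisonPlan(comps, class_set)


def enumerate_all(class_set: ClassSet, cap: int = DEFAULT_PLAN_CAP) -> ComparisonPlan:
    """Single-class pairs followed by grouped pairs, deduplicated.

    ``cap`` guards against the exponential growth of the grouped stage for
    many classes; exceeding it raises with advice to select comparisons
    explicitly.
    """
    _require_classes(class_set)
    single = enumerate_single_pairs(class_set)
    grouped = enumerate_grouped_pairs(class_set)
    seen = set()
    comps = []
    for c in list(single) + list(grouped):
        if c.key() not in seen:
            seen.add(c.key())
            comps.append(c)
    if len(comps) > cap:
        raise CombistatError(
            f"comparison plan has {len(comps)} entries (cap {cap}); "
            "select comparisons explicitly or raise the cap")
    return ComparisonPlan(comps, class_set)


def contrast_others(class_set: ClassSet, interest: str) -> Comparison:
    """The class of interest against all remaining classes pooled as "Others"."""
    _require_classes(class_set)
    if interest not in class_set:
        raise CombistatError(
            f"class {interest!r} not in class set {list(class_set.classes)}")
    others = tuple(c for c in class_set.classes if c != interest)
    return Comparison((interest,), others, b_label="Others")
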