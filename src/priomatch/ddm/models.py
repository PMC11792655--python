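"""Factor-dependency model space for the hierarchical DDM.

Each candidate model states which experimental factors each DDM parameter
depends on.  The hypothesized full model (Model 1) lets the drift rate vary by
label x match, the boundary separation and starting point by label, and the
non-decision time by match; every parameter is additionally split by group
(the friend- and self-prioritization populations are pooled separately).

The 14 reductions toggle the four within-subject condition dependencies off
one at a time and in combination (4 singles, 6 pairs, 4 triples; the model
with all four dropped is excluded).  Model 7 is pinned to the structure used
in earlier work on this task: drift per label x match, non-decision time per
match, constant boundary and starting point.  The enumeration order is a
package convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LABELS = ("self", "friend", "stranger")
MATCH_LEVELS = ("match", "nonmatch")

# the four optional within-subject dependencies
_TOGGLES = ("v_label", "a_label", "z_label", "t0_match")

# which toggles are DROPPED in models 1..15 (frozen convention; Model 7 =
# prior-study structure with a and z constant)
_DROPS = [
    (),                                   # 1: full hypothesized model
    ("t0_match",),                        # 2
    ("z_label",),                         # 3
    ("a_label",),                         # 4
    ("v_label",),                         # 5
    ("z_label", "t0_match"),              # 6
    ("a_label", "z_label"),               # 7: prior-study structure
    ("a_label", "t0_match"),              # 8
    ("v_label", "t0_match"),              # 9
    ("v_label", "z_label"),               # 10
    ("v_label", "a_label"),               # 11
    ("a_label", "z_label", "t0_match"),   # 12
    ("v_label", "z_label", "t0_match"),   # 13
    ("v_label", "a_label", "t0_match"),   # 14
    ("v_label", "a_label", "z_label"),    # 15
]


@dataclass(frozen=True)
class DDMSpec:
    """Dependency structure of (v, a, z, t0) on the design factors.

    Factor sets are frozensets over {"label", "match", "group"}.  "match" is
    always present for v (matching vs non-matching trials drive evidence in
    opposite directions) and "group" is always present for every parameter.
    """

    model_id: int
    v_factors: frozenset = field(default_factory=lambda: frozenset({"label", "match", "group"}))
    a_factors: frozenset = field(default_factory=lambda: frozenset({"label", "group"}))
    z_factors: frozenset = field(default_factory=lambda: frozenset({"label", "group"}))
    t0_factors: frozenset = field(default_factory=lambda: frozenset({"match", "group"}))
    outlier_prob: float = 0.05
    hierarchical: bool = True

    def __post_init__(self):
        if not (0.0 <= self.outlier_prob <= 0.5):
            raise ValueError("outlier_prob must lie in [0, 0.5]")
        if "match" not in self.v_factors:
            raise ValueError("drift rate must depend on match")

    def n_cells(self, param: str) -> int:
        """Number of within-group condition cells for a parameter."""
        factors = getattr(self, f"{param}_factors")
        n = 1
        if "label" in factors:
            n *= len(LABELS)
        if "match" in factors:
            n *= len(MATCH_LEVELS)
        return n

    @property
    def n_free_cells(self) -> int:
        """Total group-level mean cells per group (model complexity proxy)."""
        return sum(self.n_cells(p) for p in ("v", "a", "z", "t0"))

    def cell_index(self, param: str, label: str, match: str) -> int:
        """Flat within-group cell index of a condition for a parameter."""
        factors = getattr(self, f"{param}_factors")
        idx = 0
        if "label" in factors:
            idx = LABELS.index(label)
        if "match" in factors:
            idx = idx * len(MATCH_LEVELS) + MATCH_LEVELS.index(match)
        return idx

    def cell_name(self, param: str, cell: int) -> str:
        """Human-readable name of a within-group cell."""
        factors = getattr(self, f"{param}_factors")
        has_l = "label" in factors
        has_m = "match" in factors
        if has_l and has_m:
            lab = LABELS[cell // len(MATCH_LEVELS)]
            mat = MATCH_LEVELS[cell % len(MATCH_LEVELS)]
            return f"{lab}-{mat}"
        if has_l:
            return LABELS[cell]
        if has_m:
            return MATCH_LEVELS[cell]
        return "all"


def make_spec(model_id: int, outlier_prob: float = 0.05) -> DDMSpec:
    """Build the DDMSpec for one of the 15 candidate models (1-based id)."""
    if not 1 <= model_id <= 15:
        raise ValueError("model_id must be in 1..15")
    drops = _DROPS[model_id - 1]
    v = {"label", "match", "group"}
    a = {"label", "group"}
    z = {"label", "group"}
    t0 = {"match", "group"}
    if "v_label" in drops:
        v.discard("label")
    if "a_label" in drops:
        a.discard("label")
    if "z_label" in drops:
        z.discard("label")
    if "t0_match" in drops:
        t0.discard("match")
    return DDMSpec(
        model_id=model_id,
        v_factors=frozenset(v),
        a_factors=frozenset(a),
        z_factors=frozenset(z),
        t0_factors=frozenset(t0),
        outlier_prob=outlier_prob,
    )


def enumerate_model_space(outlier_prob: float = 0.05) -> list[DDMSpec]:
    """The hypothesized model plus its 14 one-by-one reductions."""
    return [make_spec(i, outlier_prob) for i in range(1, 16)]
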