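"""Set-logic classification of transcript clusters into biological categories.

Five named categories are derived from pairwise DE contrasts of the two
experimental designs:

* ``irradiation_depleted`` — down at 12, 24 and 72 h post-irradiation versus
  the non-irradiated control, i.e. permanently lost with the proliferating
  cells (transient stress responses recover and are excluded).
* ``proliferating_intact`` — enriched in the 4C (late-S/G2/M) over the 2C
  (G1/differentiated) FACS gate of intact adults.
* ``germline`` — proliferating-cell genes additionally enriched in intact 4C
  cells over 4C cells of juveniles and amputated heads, which lack gonads.
* ``somatic_neoblast`` — enriched in the 4C gate of intact worms, juveniles
  and heads alike, minus the germline set.
* ``stringent_neoblast`` — somatic-neoblast genes that are also
  irradiation-depleted: the intersection of the two independent approaches.

Membership uses the FDR threshold only; a greater-than-twofold change is
carried as a secondary annotation tier, mirroring how both totals are
conventionally reported ("N significant, of which M by more than twofold").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DEResult


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    alpha: float = 0.05
    fold_threshold: float = 2.0
    require_all_timepoints: bool = True
    #: germline rule: require membership in proliferating_intact
    germline_requires_intact: bool = True
    #: germline rule: 'and' = significant in both gonad-free contrasts, 'or' = either
    germline_combine: str = "and"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ClassifierError("alpha must be in (0, 1)")
        if self.fold_threshold < 1.0:
            raise ClassifierError("fold_threshold must be >= 1")
        if self.germline_combine not in {"and", "or"}:
            raise ClassifierError("germline_combine must be 'and' or 'or'")


@dataclass
class ClusterSet:
    """A named cluster set with its twofold annotation tier and provenance."""

    members: frozenset[str]
    twofold: frozenset[str]
    provenance: dict = field(default_factory=dict)


@dataclass
class CategorySets:
    irradiation_depleted: ClusterSet
    proliferating_intact: ClusterSet
    germline: ClusterSet
    somatic_neoblast: ClusterSet
    stringent_neoblast: ClusterSet

    def validate(self) -> None:
        """Structural invariants of the category system."""
        if not self.stringent_neoblast.members <= self.somatic_neoblast.members:
            raise ClassifierError("stringent_neoblast must be a subset of somatic_neoblast")
        if self.somatic_neoblast.members & self.germline.members:
            raise ClassifierError("somatic_neoblast and germline must be disjoint")
        if not self.stringent_neoblast.members <= self.irradiation_depleted.members:
            raise ClassifierError("stringent_neoblast must be irradiation-depleted")

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "irradiation_depleted": self.irradiation_depleted.members,
            "proliferating_intact": self.proliferating_intact.members,
            "germline": self.germline.members,
            "somatic_neoblast": self.somatic_neoblast.members,
            "stringent_neoblast": self.stringent_neoblast.members,
        }

    def set_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.as_dict().items()}

    def overlaps(self) -> list[list]:
        names = list(self.as_dict())
        sets = self.as_dict()
        out = []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                out.append([a, b, len(sets[a] & sets[b])])
        return out

    def to_frame(self) -> pd.DataFrame:
        """0/1 membership flags per cluster, one column per category."""
        sets = self.as_dict()
        universe = sorted(set().union(*sets.values()))
        df = pd.DataFrame(index=pd.Index(universe, name="cluster_id"))
        for name, members in sets.items():
            df[name] = [int(c in members) for c in universe]
        df["irradiation_depleted_twofold"] = [
            int(c in self.irradiation_depleted.twofold) for c in universe
        ]
        df["proliferating_intact_twofold"] = [
            int(c in self.proliferating_intact.twofold) for c in universe
        ]
        return df


def _sig(table: pd.DataFrame, alpha: float, sign: int) -> pd.Series:
    return (table["fdr"] <= alpha) & (np.sign(table["log2fc"]) == sign)


def _shared_universe(tables: list[pd.DataFrame]) -> pd.Index:
    universe = tables[0].index
    for t in tables[1:]:
        universe = universe.intersection(t.index)
    if any(len(universe) < len(t.index) for t in tables):
        warnings.warn(
            "DE tables have differing cluster universes; using the intersection",
            stacklevel=3,
        )
    return universe


def _check_contrast(result: DEResult, num_suffix: str, den_suffix: str, op: str) -> None:
    parts = result.contrast.split("_vs_")
    if len(parts) != 2 or not parts[0].endswith(num_suffix) or not parts[1].endswith(den_suffix):
        raise ClassifierError(
            f"{op}: contrast {result.contrast!r} must be oriented '*{num_suffix}_vs_*{den_suffix}'"
        )


def irradiation_depleted(
    de_12v0: DEResult,
    de_24v0: DEResult,
    de_72v0: DEResult,
    params: ClassifierParams = ClassifierParams(),
) -> ClusterSet:
    """Clusters significantly down versus control at all three post-irradiation times.

    The twofold tier marks members also below -log2(fold_threshold) log2FC in
    the 12 h contrast.
    """
    results = [de_12v0, de_24v0, de_72v0]
    for r in results:
        if r is None:
            raise ClassifierError("irradiation_depleted requires all three contrasts")
    universe = _shared_universe([r.table for r in results])
    down = pd.Series(True, index=universe)
    for r in results:
        down &= _sig(r.table.loc[universe], params.alpha, -1)
    members = frozenset(universe[down])
    lfc12 = de_12v0.table["log2fc"].reindex(universe)
    twofold = frozenset(universe[down & (lfc12 < -np.log2(params.fold_threshold))])
    return ClusterSet(
        members,
        twofold,
        {"contrasts": [r.contrast for r in results], "alpha": params.alpha},
    )


def proliferating_enriched(
    de_4c_vs_2c: DEResult, params: ClassifierParams = ClassifierParams()
) -> ClusterSet:
    """Clusters significantly enriched in the 4C (proliferating) FACS gate."""
    _check_contrast(de_4c_vs_2c, "4C", "2C", "proliferating_enriched")
    t = de_4c_vs_2c.table
    up = _sig(t, params.alpha, +1)
    members = frozenset(t.index[up])
    twofold = frozenset(t.index[up & (t["log2fc"] > np.log2(params.fold_threshold))])
    return ClusterSet(
        members, twofold, {"contrasts": [de_4c_vs_2c.contrast], "alpha": params.alpha}
    )


def germline_set(
    prolif_intact: ClusterSet,
    de_intact4c_vs_juv4c: DEResult,
    de_intact4c_vs_head4c: DEResult,
    params: ClassifierParams = ClassifierParams(),
) -> ClusterSet:
    """Proliferating-cell clusters enriched in intact 4C over both gonad-free 4C sorts."""
    for r, den in ((de_intact4c_vs_juv4c, "4C"), (de_intact4c_vs_head4c, "4C")):
        if r is None:
            raise ClassifierError("germline_set requires both gonad-free contrasts")
        _check_contrast(r, "4C", den, "germline_set")
    universe = _shared_universe([de_intact4c_vs_juv4c.table, de_intact4c_vs_head4c.table])
    up_juv = _sig(de_intact4c_vs_juv4c.table.loc[universe], params.alpha, +1)
    up_head = _sig(de_intact4c_vs_head4c.table.loc[universe], params.alpha, +1)
    combined = (up_juv & up_head) if params.germline_combine == "and" else (up_juv | up_head)
    members = set(universe[combined])
    if params.germline_requires_intact:
        members &= prolif_intact.members
    return ClusterSet(
        frozenset(members),
        frozenset(members & prolif_intact.twofold),
        {
            "contrasts": [de_intact4c_vs_juv4c.contrast, de_intact4c_vs_head4c.contrast],
            "combine": params.germline_combine,
            "requires_intact": params.germline_requires_intact,
            "alpha": params.alpha,
        },
    )


def somatic_neoblast_set(
    prolif_intact: ClusterSet,
    prolif_juvenile: ClusterSet,
    prolif_head: ClusterSet,
    germline: ClusterSet,
) -> ClusterSet:
    """(intact ∩ juvenile ∩ head 4C-enriched) minus germline-enriched clusters."""
    members = (
        prolif_intact.members & prolif_juvenile.members & prolif_head.members
    ) - germline.members
    return ClusterSet(
        frozenset(members),
        frozenset(members & prolif_intact.twofold),
        {"minus": "germline"},
    )


def stringent_neoblast_set(somatic: ClusterSet, irradiation: ClusterSet) -> ClusterSet:
    """Somatic-neoblast clusters confirmed by the irradiation approach."""
    members = somatic.members & irradiation.members
    return ClusterSet(
        frozenset(members),
        frozenset(members & somatic.twofold),
        {"intersection": ["somatic_neoblast", "irradiation_depleted"]},
    )


def build_categories(
    de_irr: dict[str, DEResult],
    de_facs: dict[str, DEResult],
    params: ClassifierParams = ClassifierParams(),
) -> CategorySets:
    """Assemble all five categories from the named contrast tables.

    ``de_irr`` must hold contrasts keyed '12h', '24h', '72h' (each versus 0 h);
    ``de_facs`` must hold 'intact', 'juvenile', 'head' (4C vs 2C per
    condition) and 'intact_vs_juvenile', 'intact_vs_head' (intact 4C vs
    gonad-free 4C).  Invariants are asserted on the result.
    """
    depleted = irradiation_depleted(de_irr["12h"], de_irr["24h"], de_irr["72h"], params)
    prolif = {c: proliferating_enriched(de_facs[c], params) for c in ("intact", "juvenile", "head")}
    germ = germline_set(
        prolif["intact"], de_facs["intact_vs_juvenile"], de_facs["intact_vs_head"], params
    )
    somatic = somatic_neoblast_set(prolif["intact"], prolif["juvenile"], prolif["head"], germ)
    stringent = stringent_neoblast_set(somatic, depleted)
    categories = CategorySets(depleted, prolif["intact"], germ, somatic, stringent)
    categories.validate()
    return categories
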