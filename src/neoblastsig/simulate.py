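"""Seeded synthetic data emulating irradiation-ablation and FACS cell-sorting designs.

The generator models a flatworm as a mixture of three cell compartments —
differentiated cells, somatic neoblasts (the only proliferating somatic cells)
and proliferating germline cells — and derives per-sample expected counts from
an explicit cell-composition mixture over four gene programs:

* ``housekeeping``  expressed in every compartment,
* ``neoblast``      expressed only in somatic neoblasts,
* ``germline``      expressed only in proliferating germline cells,
* ``tissue``        expressed only in differentiated cells.

Two experimental designs are emulated.  In the irradiation time course a
lethal gamma dose kills all proliferating cells, so from 12 h post-irradiation
onward both proliferating compartments are absent and transcripts specific to
them drop to zero expectation.  In the FACS design, Hoechst-based sorting
yields a 2C gate (G1, essentially differentiated cells) and a 4C gate
(late-S/G2/M, proliferating cells); sorting juveniles or amputated heads —
conditions without gonads — restricts the 4C gate to somatic neoblasts.

Counts are negative binomial (variance = mu + phi * mu**2) with an optional
multiplicative batch factor on the log scale, giving unwanted-variation
structure for RUV to recover.  Transcript sequences are uniform random DNA
with a trans-splice leader planted verbatim on a configurable fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import io as nio

#: Trans-splice leader of Macrostomum lignano (44 nt).
SL_LEADER = "CCGTAAAGACGGTCTCTTACTGCGAAGACTCAATTTATTGCATG"

PROGRAMS = ("housekeeping", "neoblast", "germline", "tissue")
CELL_TYPES = ("differentiated", "somatic_neoblast", "germline_proliferating")

#: Which cell compartments express each gene program.
PROGRAM_EXPRESSION = {
    "housekeeping": frozenset(CELL_TYPES),
    "neoblast": frozenset({"somatic_neoblast"}),
    "germline": frozenset({"germline_proliferating"}),
    "tissue": frozenset({"differentiated"}),
}

#: Reference library size at which program base means are expressed.
REFERENCE_LIBRARY = 1_000_000

IRRADIATION_TIMEPOINTS = (0, 12, 24, 72)
FACS_CONDITIONS = ("intact", "juvenile", "head")


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class GeneProgram:
    """Expression program of a transcript cluster.

    base_mean is the expected count at the reference library size in cells
    that express the program; dispersion is the NB phi (var = mu + phi mu^2).
    """

    program_label: str
    base_mean: float
    dispersion: float

    def __post_init__(self):
        if self.program_label not in PROGRAMS:
            raise SimulationError(f"unknown program label {self.program_label!r}")
        if not self.base_mean > 0:
            raise SimulationError("base_mean must be positive")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")


@dataclass(frozen=True)
class CellComposition:
    """Fractions of the three cell compartments; must sum to one."""

    fractions: dict[str, float]

    def __post_init__(self):
        unknown = set(self.fractions) - set(CELL_TYPES)
        if unknown:
            raise SimulationError(f"unknown cell types {sorted(unknown)}")
        vals = [self.fractions.get(ct, 0.0) for ct in CELL_TYPES]
        if any(v < 0 for v in vals):
            raise SimulationError("cell fractions must be >= 0")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise SimulationError(f"cell fractions sum to {sum(vals)}, expected 1")

    def __getitem__(self, cell_type: str) -> float:
        return self.fractions.get(cell_type, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self[ct] for ct in CELL_TYPES], dtype=float)


#: Whole-worm composition: 6.5% of cells proliferate, split 70/30 between
#: somatic neoblasts and the germline.
DEFAULT_BASE_COMPOSITION = CellComposition(
    {"differentiated": 0.935, "somatic_neoblast": 0.045, "germline_proliferating": 0.020}
)


def _default_programs() -> tuple[GeneProgram, ...]:
    return (
        GeneProgram("housekeeping", 100.0, 0.1),
        GeneProgram("neoblast", 400.0, 0.1),
        GeneProgram("germline", 400.0, 0.1),
        GeneProgram("tissue", 100.0, 0.1),
    )


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the study layout: an irradiation time course at
    0/12/24/72 h and 2C/4C FACS sorts of intact adults, 1-day juveniles and
    amputated heads, three replicates each.
    """

    n_clusters: int = 10_000
    n_transcripts: int = 2_000
    program_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "housekeeping": 0.57,
            "neoblast": 0.05,
            "germline": 0.08,
            "tissue": 0.30,
        }
    )
    programs: tuple[GeneProgram, ...] = field(default_factory=_default_programs)
    base_mean_sdlog: float = 0.6
    base_composition: CellComposition = field(
        default_factory=lambda: DEFAULT_BASE_COMPOSITION
    )
    library_size: int = REFERENCE_LIBRARY
    replicates: int = 3
    designs: tuple[str, ...] = ("irradiation", "facs")
    timepoints_h: tuple[int, ...] = IRRADIATION_TIMEPOINTS
    facs_conditions: tuple[str, ...] = FACS_CONDITIONS
    batch_factor_sd: float = 0.2
    irradiation_leakage: float = 0.0
    leader_fraction: float = 0.3
    leader_sequence: str = SL_LEADER
    transcript_length_range: tuple[int, int] = (200, 1500)
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters <= 0:
            raise SimulationError("n_clusters must be positive")
        if self.n_transcripts < 0:
            raise SimulationError("n_transcripts must be >= 0")
        if self.replicates <= 0:
            raise SimulationError("replicates must be positive")
        props = self.program_proportions
        if set(props) - set(PROGRAMS):
            raise SimulationError("program_proportions has unknown labels")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise SimulationError("program_proportions must sum to 1")
        if not 0.0 <= self.leader_fraction <= 1.0:
            raise SimulationError("leader_fraction must be in [0, 1]")
        if set(self.leader_sequence) - set("ACGT"):
            raise SimulationError("leader_sequence must be over {A,C,G,T}")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise SimulationError("invalid transcript_length_range")
        if len(self.leader_sequence) > lo:
            raise SimulationError("leader longer than minimum transcript length")
        unknown = set(self.designs) - {"irradiation", "facs"}
        if unknown:
            raise SimulationError(f"unknown designs {sorted(unknown)}")
        if self.batch_factor_sd < 0:
            raise SimulationError("batch_factor_sd must be >= 0")
        if not 0.0 <= self.irradiation_leakage <= 1.0:
            raise SimulationError("irradiation_leakage must be in [0, 1]")

    def program_by_label(self, label: str) -> GeneProgram:
        for p in self.programs:
            if p.program_label == label:
                return p
        raise SimulationError(f"no GeneProgram for label {label!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator."""

    cluster_program: dict[str, str]
    transcript_leader: dict[str, bool]
    batch_factor: pd.Series  # per-sample latent factor (unit variance scale)


@dataclass
class SyntheticDataset:
    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: SyntheticTruth
    transcripts: list[SeqRecord]
    config: SimulationConfig


def composition_for_sample(
    design: str,
    condition: str,
    timepoint_h: int | None = None,
    gate: str | None = None,
    base: CellComposition = DEFAULT_BASE_COMPOSITION,
    leakage: float = 0.0,
) -> CellComposition:
    """Cell composition of one sample under the ablation/sorting designs.

    Irradiation kills all proliferating cells within 12 h, so any
    post-irradiation timepoint returns the base composition with both
    proliferating compartments removed (times ``leakage``, default 0) and
    differentiated cells renormalised.  FACS 2C gates contain differentiated
    cells only; 4C gates contain the proliferating compartments, which for
    gonad-free juveniles and amputated heads means somatic neoblasts alone.
    """
    if design == "irradiation":
        if condition not in {"control", "irradiated"}:
            raise SimulationError(f"unknown irradiation condition {condition!r}")
        if timepoint_h is None:
            raise SimulationError("irradiation samples require a timepoint")
        if timepoint_h < 0:
            raise SimulationError("negative timepoint")
        if timepoint_h == 0 or condition == "control":
            return base
        neo = base["somatic_neoblast"] * leakage
        germ = base["germline_proliferating"] * leakage
        diff = 1.0 - neo - germ
        return CellComposition(
            {
                "differentiated": diff,
                "somatic_neoblast": neo,
                "germline_proliferating": germ,
            }
        )
    if design == "facs":
        if condition not in FACS_CONDITIONS:
            raise SimulationError(f"unknown FACS condition {condition!r}")
        if gate not in {"2C", "4C"}:
            raise SimulationError(f"unknown FACS gate {gate!r}")
        if gate == "2C":
            return CellComposition(
                {
                    "differentiated": 1.0,
                    "somatic_neoblast": 0.0,
                    "germline_proliferating": 0.0,
                }
            )
        if condition == "intact":
            neo = base["somatic_neoblast"]
            germ = base["germline_proliferating"]
            total = neo + germ
            if total <= 0:
                raise SimulationError("base composition has no proliferating cells")
            return CellComposition(
                {
                    "differentiated": 0.0,
                    "somatic_neoblast": neo / total,
                    "germline_proliferating": germ / total,
                }
            )
        # juveniles and amputated heads lack gonads: 4C gate is pure neoblast
        return CellComposition(
            {
                "differentiated": 0.0,
                "somatic_neoblast": 1.0,
                "germline_proliferating": 0.0,
            }
        )
    raise SimulationError(f"unknown design {design!r}")


def build_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the configured designs (one row per library)."""
    rows = []
    if "irradiation" in config.designs:
        for t in config.timepoints_h:
            cond = "control" if t == 0 else "irradiated"
            for r in range(1, config.replicates + 1):
                rows.append((f"irr_{t}h_r{r}", "irradiation", cond, t, "NA", r))
    if "facs" in config.designs:
        for cond in config.facs_conditions:
            for gate in ("2C", "4C"):
                for r in range(1, config.replicates + 1):
                    rows.append((f"facs_{cond}_{gate}_r{r}", "facs", cond, -1, gate, r))
    sheet = pd.DataFrame(
        rows,
        columns=["sample_id", "dataset", "condition", "timepoint_h", "gate", "replicate"],
    )
    return sheet.set_index("sample_id", drop=False)


def _sample_composition(config: SimulationConfig, row: pd.Series) -> CellComposition:
    if row["dataset"] == "irradiation":
        return composition_for_sample(
            "irradiation",
            row["condition"],
            timepoint_h=int(row["timepoint_h"]),
            base=config.base_composition,
            leakage=config.irradiation_leakage,
        )
    return composition_for_sample(
        "facs", row["condition"], gate=row["gate"], base=config.base_composition
    )


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def expected_counts(
    config: SimulationConfig,
    programs: np.ndarray,
    base_means: np.ndarray,
    sheet: pd.DataFrame,
    loadings: np.ndarray,
    batch: np.ndarray,
) -> np.ndarray:
    """Expected count matrix (clusters x samples) under the mixture model."""
    mix = np.empty((len(PROGRAMS), len(sheet)))
    label_idx = {lab: i for i, lab in enumerate(PROGRAMS)}
    for j, (_, row) in enumerate(sheet.iterrows()):
        comp = _sample_composition(config, row)
        for lab, i in label_idx.items():
            mix[i, j] = sum(comp[ct] for ct in PROGRAM_EXPRESSION[lab])
    prog_idx = np.array([label_idx[p] for p in programs])
    lib_scale = config.library_size / REFERENCE_LIBRARY
    mu = lib_scale * base_means[:, None] * mix[prog_idx, :]
    if config.batch_factor_sd > 0:
        mu = mu * np.exp(config.batch_factor_sd * np.outer(loadings, batch))
    return mu


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a NB count matrix plus sample sheet and ground truth.

    Expected count of cluster g in sample j is ``library_size_j / 1e6 *
    base_mean_g * (sum of compartment fractions expressing g's program) *
    exp(batch_factor_sd * loading_g * factor_j)``; counts are NB with the
    program's dispersion.  Identical seeds yield identical output.
    """
    rng_prog, rng_mean, rng_batch, rng_counts, _ = _rng_streams(config.seed, 5)
    sheet = build_sample_sheet(config)
    if sheet.empty:
        raise SimulationError("no designs configured")

    labels = np.array(PROGRAMS)
    props = np.array([config.program_proportions.get(l, 0.0) for l in PROGRAMS])
    programs = rng_prog.choice(labels, size=config.n_clusters, p=props)
    cluster_ids = [f"MLC{i:05d}" for i in range(config.n_clusters)]

    prog_mean = {p.program_label: p.base_mean for p in config.programs}
    prog_disp = {p.program_label: p.dispersion for p in config.programs}
    base_means = np.array([prog_mean[p] for p in programs]) * np.exp(
        rng_mean.normal(0.0, config.base_mean_sdlog, size=config.n_clusters)
    )
    dispersions = np.array([prog_disp[p] for p in programs])

    loadings = rng_batch.normal(size=config.n_clusters)
    batch = rng_batch.normal(size=len(sheet))

    mu = expected_counts(config, programs, base_means, sheet, loadings, batch)

    # gamma-Poisson mixture: NB with var = mu + phi mu^2
    phi = np.clip(dispersions, 0.0, None)[:, None]
    counts = np.empty_like(mu, dtype=np.int64)
    poisson_like = phi < 1e-12
    lam = np.where(poisson_like, mu, 0.0)
    shape = np.where(poisson_like, 1.0, 1.0 / np.where(poisson_like, 1.0, phi))
    lam_nb = rng_counts.gamma(shape, np.where(poisson_like, 0.0, mu * phi))
    lam = lam + np.where(poisson_like, 0.0, lam_nb)
    counts = rng_counts.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=cluster_ids, columns=sheet.index)
    counts_df.index.name = "cluster_id"
    truth = SyntheticTruth(
        cluster_program=dict(zip(cluster_ids, programs)),
        transcript_leader={},
        batch_factor=pd.Series(batch, index=sheet.index, name="batch_factor"),
    )
    return counts_df, sheet, truth


def generate_transcripts(
    config: SimulationConfig,
) -> tuple[list[SeqRecord], dict[str, bool]]:
    """Uniform-random transcripts with the leader planted on a Bernoulli subset."""
    *_, rng = _rng_streams(config.seed, 5)
    lo, hi = config.transcript_length_range
    bases = np.array(list("ACGT"))
    records: list[SeqRecord] = []
    flags: dict[str, bool] = {}
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    planted = rng.random(config.n_transcripts) < config.leader_fraction
    for i in range(config.n_transcripts):
        tid = f"MLT{i:05d}"
        seq = "".join(rng.choice(bases, size=lengths[i]))
        if planted[i]:
            seq = config.leader_sequence + seq
        records.append(SeqRecord(Seq(seq), id=tid, description=""))
        flags[tid] = bool(planted[i])
    return records, flags


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic study: counts, sample sheet, transcripts and truth."""
    counts, sheet, truth = simulate_counts(config)
    records, flags = generate_transcripts(config)
    truth.transcript_leader = flags
    return SyntheticDataset(counts, sheet, truth, records, config)


def _config_echo(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["base_composition"] = dict(config.base_composition.fractions)
    d["programs"] = [dataclasses.asdict(p) for p in config.programs]
    d["designs"] = list(config.designs)
    d["timepoints_h"] = list(config.timepoints_h)
    d["facs_conditions"] = list(config.facs_conditions)
    d["transcript_length_range"] = list(config.transcript_length_range)
    return d


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write FASTA, counts, sample sheet, truth and config echo; return manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "transcripts": directory / "transcripts.fasta",
        "counts": directory / "counts.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    nio.write_fasta(dataset.transcripts, manifest["transcripts"])
    nio.write_counts(dataset.counts, manifest["counts"])
    dataset.samples.to_csv(manifest["samples"], sep="\t", index=False)
    truth_rows = [
        {"id": cid, "kind": "cluster", "label": lab}
        for cid, lab in dataset.truth.cluster_program.items()
    ] + [
        {"id": tid, "kind": "transcript", "label": "leader" if f else "no_leader"}
        for tid, f in dataset.truth.transcript_leader.items()
    ]
    pd.DataFrame(truth_rows, columns=["id", "kind", "label"]).to_csv(
        manifest["truth"], sep="\t", index=False
    )
    with open(manifest["config"], "w") as fh:
        yaml.safe_dump(_config_echo(dataset.config), fh, sort_keys=True)
    return manifest
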