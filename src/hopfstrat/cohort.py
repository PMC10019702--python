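"""Fully synthetic two-subtype cohort: connectome, subject FCs, behavior.

The generator emulates the structure of a 42-patient randomized
sham-controlled stimulation trial stratified into two dynamical subtypes:
20 DEP1 / 22 DEP2 subjects allocated 10/10/10/12 over sham/active arms.
Subject FC matrices are simulated from the oscillator model at each subtype's
ground-truth parameter set (each subject with its own noise seed) and
perturbed symmetrically in Fisher-z space.  Ordinal symptom items (MADRS-S,
BPRS-AFF, CAINS) arise from a thresholded latent Gaussian with subtype shifts
at baseline and treatment-by-subtype shifts at follow-up; TMT completion times
are continuous on the log-seconds scale.  Every random draw derives from the
spec seed, so regeneration is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import derive_seed
from .clinical import SCALES, TMT_TASKS
from .connectome import StructuralConnectome, generate_synthetic_connectome
from .oscillator import (
    ModelParameters,
    SimulationConfig,
    draw_intrinsic_frequencies,
    extract_bold,
    simulate_network,
)
from .signals import FCMatrix, bandpass_dct, compute_fc, fisher_z

__all__ = [
    "DEP1_TRUTH",
    "DEP2_TRUTH",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_behavior_only",
    "truth_report",
    "label_accuracy",
]

#: ground-truth parameter sets for the two dynamical subtypes
DEP1_TRUTH = ModelParameters(A=-0.090, G=0.010, F=0.7, M=0.49)
DEP2_TRUTH = ModelParameters(A=0.020, G=0.035, F=0.4, M=0.46)

#: latent-scale baseline severity shifts (positive = DEP1 more severe)
DEFAULT_BASELINE_SHIFTS = {
    "madrs2": 0.8, "madrs6": 0.8, "madrs4": -0.8, "madrs7": -0.8,
    "bprs3": 0.8, "bprs1": -0.6, "bprs4": -0.6,
    "cains7": 0.8, "cains8": 0.8, "cains11": 0.8,
    "cains3": -0.6, "cains9": -0.8, "cains12": -0.6, "cains13": -0.6,
}
#: extra follow-up improvement (score units) for active-arm DEP2 subjects
DEFAULT_INTERACTION_SHIFTS = {
    "madrs1": 1.0, "madrs6": 1.0, "bprs3": 0.8, "bprs4": 0.8, "cains5": 1.0,
}

#: test-retest correlation of the latent severity between sessions
SESSION_RHO = 0.7


@dataclass
class SyntheticCohortSpec:
    n_subjects: int = 42
    n_dep1: int = 20  # subtype proportion 20/42
    params_dep1: ModelParameters = DEP1_TRUTH
    params_dep2: ModelParameters = DEP2_TRUTH
    subject_param_jitter: dict[str, float] = field(default_factory=dict)
    fc_noise_sd: float = 0.05
    baseline_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SHIFTS)
    )
    interaction_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERACTION_SHIFTS)
    )
    fc_mode: str = "resimulate"  # "resimulate" | "shared"
    seed: int = 0

    def null_effects(self) -> "SyntheticCohortSpec":
        """Copy of this spec with all behavioral effects removed."""
        return replace(self, baseline_shifts={}, interaction_shifts={})

    def validate(self) -> None:
        if not 0 < self.n_dep1 < self.n_subjects:
            raise ValueError("n_dep1 must be strictly between 0 and n_subjects")
        if self.fc_noise_sd < 0:
            raise ValueError("fc_noise_sd must be nonnegative")
        if self.fc_mode not in ("resimulate", "shared"):
            raise ValueError("fc_mode must be 'resimulate' or 'shared'")
        valid = {f"{s}{i}" for s, (n, _) in SCALES.items() for i in range(1, n + 1)}
        valid |= set(TMT_TASKS)
        for table_name in ("baseline_shifts", "interaction_shifts"):
            bad = set(getattr(self, table_name)) - valid
            if bad:
                raise ValueError(f"unknown item(s) in {table_name}: {sorted(bad)}")


@dataclass
class SyntheticCohort:
    connectome: StructuralConnectome
    omega0: np.ndarray
    subject_fcs: list[FCMatrix]
    cohort_table: pd.DataFrame
    true_subtypes: dict[str, str]
    spec: SyntheticCohortSpec
    generation_log: dict = field(default_factory=dict)


def _layout(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Subject metadata with the trial's treatment-by-subtype cell layout.

    With the defaults (42 subjects, 20 DEP1) the active arm holds 10 DEP1 and
    12 DEP2, the sham arm 10 and 10; other sizes split each subtype as evenly
    as possible with the extra subject going to the active arm.
    """
    n, n1 = spec.n_subjects, spec.n_dep1
    ids = [f"sub_{i:03d}" for i in range(n)]
    subtype = np.array(["DEP1"] * n1 + ["DEP2"] * (n - n1))
    treatment = np.empty(n, dtype=object)
    active_frac = 22.0 / 42.0  # the trial randomized 22 of 42 to active
    for label in ("DEP1", "DEP2"):
        idx = np.flatnonzero(subtype == label)
        n_active = int(np.floor(idx.size * active_frac + 0.5))
        chosen = rng.choice(idx, size=n_active, replace=False)
        treatment[idx] = "sham"
        treatment[chosen] = "active"
    age = np.clip(np.round(rng.normal(29.0, 9.4, size=n)), 18, 59).astype(int)
    sex = np.array(["F"] * (n // 2) + ["M"] * (n - n // 2))
    rng.shuffle(sex)
    return pd.DataFrame(
        {"subject_id": ids, "treatment": treatment, "subtype": subtype,
         "age": age, "sex": sex}
    )


def _ordinal_scores(latent: np.ndarray, n_levels: int) -> np.ndarray:
    """Equally-spaced thresholding of a latent severity onto {0..n_levels}."""
    center = n_levels / 2.0
    return np.clip(np.round(center + latent), 0, n_levels).astype(int)


def _behavior(meta: pd.DataFrame, spec: SyntheticCohortSpec,
              rng: np.random.Generator) -> pd.DataFrame:
    df = meta.copy()
    n = len(df)
    dep1 = (df["subtype"] == "DEP1").to_numpy(dtype=float)
    active = (df["treatment"] == "active").to_numpy(dtype=float)
    for scale, (n_items, n_levels) in SCALES.items():
        for i in range(1, n_items + 1):
            stem = f"{scale}{i}"
            shift = spec.baseline_shifts.get(stem, 0.0)
            gain = spec.interaction_shifts.get(stem, 0.0)
            e_base = rng.standard_normal(n)
            e_fu = rng.standard_normal(n)
            lat_base = shift * dep1 + e_base
            lat_fu = (
                shift * dep1
                + SESSION_RHO * e_base
                + np.sqrt(1 - SESSION_RHO**2) * e_fu
                - gain * active * (1.0 - dep1)  # extra improvement: active DEP2
            )
            df[f"{stem}_base"] = _ordinal_scores(lat_base, n_levels)
            df[f"{stem}_fu"] = _ordinal_scores(lat_fu, n_levels)
    for task, mean in zip(TMT_TASKS, (1.75, 1.85)):  # log10 seconds
        e_base = rng.normal(0.0, 0.2, n)
        e_fu = rng.normal(0.0, 0.2, n)
        gain = spec.interaction_shifts.get(task, 0.0)
        df[f"{task}_base"] = np.round(mean + e_base, 3)
        df[f"{task}_fu"] = np.round(
            mean + SESSION_RHO * e_base + np.sqrt(1 - SESSION_RHO**2) * e_fu
            - gain * active * (1.0 - dep1), 3
        )
    return df


def generate_behavior_only(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Behavioral table alone (no FC simulation) — the fast path for
    statistical calibration studies."""
    spec.validate()
    meta = _layout(spec, np.random.default_rng(derive_seed(spec.seed, 11)))
    return _behavior(meta, spec, np.random.default_rng(derive_seed(spec.seed, 13)))


def _jittered(params: ModelParameters, jitter: dict[str, float],
              rng: np.random.Generator) -> ModelParameters:
    if not jitter:
        return params
    vals = {}
    for axis in ("A", "G", "F", "M"):
        sd = jitter.get(axis, 0.0)
        v = getattr(params, axis) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        vals[axis] = v if axis == "A" else max(v, 0.0)
    return ModelParameters(vals["A"], vals["G"], vals["F"], vals["M"], params.beta)


def generate_cohort(
    spec: SyntheticCohortSpec,
    sim_config: SimulationConfig | None = None,
    connectome: StructuralConnectome | None = None,
    omega0: np.ndarray | None = None,
    base_fcs: dict[str, FCMatrix] | None = None,
) -> SyntheticCohort:
    """Generate connectome, per-subject FCs and the behavioral table.

    Two FC modes:

    ``resimulate`` (default)
        Each subject is simulated at its subtype's (optionally jittered)
        parameter set with a unique noise seed.
    ``shared``
        One model FC realization per subtype — supplied via ``base_fcs``
        (keys "DEP1"/"DEP2", e.g. the grid bank's FCs at the truth points) or
        simulated here once per subtype — shared by all subjects of that
        subtype.

    Either way the Fisher-z FC then receives a per-subject symmetric Gaussian
    perturbation of SD ``fc_noise_sd``.
    """
    spec.validate()
    sim_config = sim_config or SimulationConfig()
    if connectome is None:
        connectome = generate_synthetic_connectome(seed=derive_seed(spec.seed, 3))
    if omega0 is None:
        omega0 = draw_intrinsic_frequencies(connectome.n_regions,
                                            seed=derive_seed(spec.seed, 5))

    meta = _layout(spec, np.random.default_rng(derive_seed(spec.seed, 11)))
    table = _behavior(meta, spec, np.random.default_rng(derive_seed(spec.seed, 13)))

    def _simulate_fc(params: ModelParameters, seed: int) -> FCMatrix:
        cfg = SimulationConfig(sim_config.dt, sim_config.duration,
                               sim_config.burn_in, sim_config.sample_interval,
                               seed=seed)
        traj = simulate_network(params, connectome, omega0, cfg)
        return fisher_z(compute_fc(bandpass_dct(extract_bold(traj))))

    if spec.fc_mode == "shared" and base_fcs is None:
        base_fcs = {
            "DEP1": _simulate_fc(spec.params_dep1, derive_seed(spec.seed, 29)),
            "DEP2": _simulate_fc(spec.params_dep2, derive_seed(spec.seed, 31)),
        }

    iu = np.triu_indices(connectome.n_regions, k=1)
    fcs: list[FCMatrix] = []
    for i, row in meta.iterrows():
        if spec.fc_mode == "shared":
            fcz = base_fcs[row["subtype"]]
        else:
            truth = spec.params_dep1 if row["subtype"] == "DEP1" else spec.params_dep2
            jrng = np.random.default_rng(derive_seed(spec.seed, 17, i))
            params = _jittered(truth, spec.subject_param_jitter, jrng)
            fcz = _simulate_fc(params, derive_seed(spec.seed, 19, i))
        vals = fcz.values.copy()
        if spec.fc_noise_sd > 0:
            nrng = np.random.default_rng(derive_seed(spec.seed, 23, i))
            noise = np.zeros_like(vals)
            noise[iu] = nrng.normal(0.0, spec.fc_noise_sd, iu[0].size)
            vals += noise + noise.T
        fcs.append(FCMatrix(vals, "fisher_z",
                            {"kind": "empirical", "subject_id": row["subject_id"],
                             "true_subtype": row["subtype"]}))

    truth = dict(zip(meta["subject_id"], meta["subtype"]))
    log = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "n_dep1": spec.n_dep1,
        "params_dep1": spec.params_dep1.as_tuple(),
        "params_dep2": spec.params_dep2.as_tuple(),
        "fc_noise_sd": spec.fc_noise_sd,
        "fc_mode": spec.fc_mode,
        "sim_config": (sim_config.dt, sim_config.duration, sim_config.burn_in,
                       sim_config.sample_interval),
    }
    return SyntheticCohort(connectome, omega0, fcs, table, truth, spec, log)


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Ground truth per subject: label, generating parameters, injected effects."""
    spec = cohort.spec
    rows = []
    for sid, label in cohort.true_subtypes.items():
        p = spec.params_dep1 if label == "DEP1" else spec.params_dep2
        rows.append({"subject_id": sid, "true_subtype": label,
                     "A": p.A, "G": p.G, "F": p.F, "M": p.M})
    df = pd.DataFrame(rows)
    df.attrs["baseline_shifts"] = dict(spec.baseline_shifts)
    df.attrs["interaction_shifts"] = dict(spec.interaction_shifts)
    return df


def label_accuracy(assignments, cohort: SyntheticCohort) -> float:
    """Fraction of subjects whose assigned subtype matches the ground truth."""
    truth = cohort.true_subtypes
    hits = sum(1 for a in assignments if truth.get(a.subject_id) == a.subtype)
    return hits / len(assignments)
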