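"""Synthetic microarray study generator.

Emulates the structure of a transcribed-ultraconserved-region (T-UCR)
expression study: 481 ultraconserved regions probed in sense (``uc.<n>+``)
and antisense (``uc.<n>+A``) orientation (962 features), quadruplicate
spots per probe, and three sample groups — 17 normal bladder epithelium
controls (NBE), 12 low-grade (LG) and 12 high-grade (HG) bladder cancer
patients.

The generative model, on the log2 scale:

* every probe has its own baseline intensity, drawn once;
* non-planted probes are exchangeable across groups (pure within-group
  Gaussian noise, shared distribution);
* a configurable set of planted differential probes is shifted by
  ``effect_lg`` / ``effect_hg`` log2 units in the LG / HG groups, with a
  random up/down direction per probe;
* the cancer samples are partitioned into planted patient subgroups; each
  subgroup adds its own +/- ``subgroup_effect`` signature over the planted
  probes (the structure hierarchical clustering is asked to recover), and
  survival times are exponential with a subgroup-specific mean, subject to
  uniform administrative censoring.

Ground truth (which probes were planted, with their shifts, and each
patient's subgroup) is returned alongside the data for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import validate_expression_matrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate",
           "generate_replicated", "probe_names"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the reference study design: 481 UCRs (962 sense +
    antisense probes), 17/12/12 NBE/LG/HG samples, quadruplicate spots.
    """

    n_ucrs: int = 481
    n_nbe: int = 17
    n_lg: int = 12
    n_hg: int = 12
    #: number of planted differentially expressed probes
    n_de: int = 24
    #: mean log2 shift of planted probes in LG vs NBE (sign randomized per probe)
    effect_lg: float = 2.0
    #: mean log2 shift of planted probes in HG vs NBE
    effect_hg: float = 2.5
    #: within-group sd of log2 expression
    noise_sd: float = 1.0
    #: grand mean log2 intensity
    baseline_mean: float = 8.0
    #: sd of per-probe baseline offsets around the grand mean
    baseline_probe_sd: float = 1.5
    #: spots per probe on the array
    replicate_spots: int = 4
    #: spot-level measurement noise sd (0 = noise-free spots)
    replicate_sd: float = 0.5
    #: mean survival months per planted patient subgroup; its length sets
    #: the number of subgroups among the LG+HG samples
    survival_scale_by_group: tuple[float, ...] = (4.0, 15.0, 60.0, 200.0)
    #: magnitude of the per-subgroup +/- expression signature on planted probes
    subgroup_effect: float = 1.0
    #: probability that a patient's event is censored (administrative)
    censoring_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        counts = {"n_ucrs": self.n_ucrs, "n_nbe": self.n_nbe,
                  "n_lg": self.n_lg, "n_hg": self.n_hg,
                  "replicate_spots": self.replicate_spots}
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value}")
        if not 0 <= self.n_de <= 2 * self.n_ucrs:
            raise ValueError(
                f"n_de must be in [0, 2*n_ucrs={2 * self.n_ucrs}], got {self.n_de}")
        if self.noise_sd <= 0 or self.baseline_probe_sd <= 0:
            raise ValueError("noise_sd and baseline_probe_sd must be > 0")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")
        if len(self.survival_scale_by_group) < 1:
            raise ValueError("survival_scale_by_group must be non-empty")
        if any(m <= 0 for m in self.survival_scale_by_group):
            raise ValueError("survival means must be > 0")
        if self.subgroup_effect < 0 or self.effect_lg < 0 or self.effect_hg < 0:
            raise ValueError("effect magnitudes must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study.

    ``de_probes`` maps each planted probe id to its true (lg_shift, hg_shift)
    in log2 units, sign included.  ``subgroup_of_sample`` maps each cancer
    sample to its planted patient subgroup (1-based).
    """

    de_probes: dict[str, tuple[float, float]] = field(default_factory=dict)
    subgroup_of_sample: dict[str, int] = field(default_factory=dict)

    @property
    def de_probe_ids(self) -> set[str]:
        return set(self.de_probes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_probes": {p: list(sh) for p, sh in self.de_probes.items()},
            "subgroup_of_sample": self.subgroup_of_sample,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def probe_names(n_ucrs: int) -> list[str]:
    """Sense/antisense probe ids: uc.1+, uc.1+A, uc.2+, uc.2+A, ..."""
    out = []
    for i in range(1, n_ucrs + 1):
        out.append(f"uc.{i}+")
        out.append(f"uc.{i}+A")
    return out


def _sample_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Sample ids and group labels, NBE first then LG then HG."""
    ids, groups = [], []
    for prefix, n, group in (("N", config.n_nbe, "NBE"),
                             ("L", config.n_lg, "LG"),
                             ("H", config.n_hg, "HG")):
        for j in range(1, n + 1):
            ids.append(f"{prefix}{j:02d}")
            groups.append(group)
    return ids, groups


def generate(config: SyntheticConfig | None = None,
             ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic study: (expression matrix, annotation, truth).

    Identical config (including seed) gives bit-identical output.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    probes = probe_names(config.n_ucrs)
    samples, groups = _sample_ids(config)
    n_probes, n_samples = len(probes), len(samples)
    groups_arr = np.asarray(groups)

    baseline = config.baseline_mean + rng.normal(
        0.0, config.baseline_probe_sd, size=n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_probes, n_samples))

    # planted differential probes, random up/down direction per probe
    de_idx = np.sort(rng.choice(n_probes, size=config.n_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_de)
    lg_mask = groups_arr == "LG"
    hg_mask = groups_arr == "HG"
    values[np.ix_(de_idx, np.flatnonzero(lg_mask))] += \
        (signs * config.effect_lg)[:, None]
    values[np.ix_(de_idx, np.flatnonzero(hg_mask))] += \
        (signs * config.effect_hg)[:, None]

    # planted patient subgroups among the cancer samples
    n_sub = len(config.survival_scale_by_group)
    blca_idx = np.flatnonzero(lg_mask | hg_mask)
    n_blca = blca_idx.size
    if n_sub > n_blca:
        raise ValueError(
            f"{n_sub} survival subgroups but only {n_blca} cancer samples")
    sub_labels = np.array([(i % n_sub) + 1 for i in range(n_blca)])
    rng.shuffle(sub_labels)
    signatures = rng.choice([-1.0, 1.0], size=(n_sub, config.n_de)) \
        * config.subgroup_effect
    for pos, col in enumerate(blca_idx):
        values[de_idx, col] += signatures[sub_labels[pos] - 1]

    # survival: exponential per subgroup, uniform administrative censoring
    surv = np.full(n_samples, np.nan)
    event = np.full(n_samples, np.nan)
    means = np.asarray(config.survival_scale_by_group, dtype=float)
    true_times = rng.exponential(means[sub_labels - 1])
    censored = rng.random(n_blca) < config.censoring_fraction
    obs_times = np.where(censored, true_times * rng.random(n_blca), true_times)
    surv[blca_idx] = obs_times
    event[blca_idx] = (~censored).astype(float)

    matrix = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                          columns=samples)
    validate_expression_matrix(matrix, source="synthetic matrix")
    annotation = pd.DataFrame(
        {"group": groups, "survival_months": surv, "event": event},
        index=pd.Index(samples, name="sample_id"))

    truth = SyntheticTruth(
        de_probes={probes[i]: (float(s * config.effect_lg),
                               float(s * config.effect_hg))
                   for i, s in zip(de_idx, signs)},
        subgroup_of_sample={samples[col]: int(sub_labels[pos])
                            for pos, col in enumerate(blca_idx)},
    )
    return matrix, annotation, truth


def generate_replicated(config: SyntheticConfig | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, list[str]],
                                   pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a spot-level study with ``replicate_spots`` rows per probe.

    Returns ``(spot_matrix, replicate_map, probe_matrix, annotation, truth)``
    where each spot row is the probe-level value plus independent Gaussian
    noise of sd ``replicate_sd``; collapsing the spot matrix recovers the
    probe-level matrix up to that noise (exactly when ``replicate_sd == 0``).
    """
    config = config or SyntheticConfig()
    config.validate()
    probe_matrix, annotation, truth = generate(config)
    # independent stream so the probe-level draw matches generate() exactly
    rng = np.random.default_rng([config.seed, 104729])

    k = config.replicate_spots
    replicate_map = {probe: [f"{probe}_s{j}" for j in range(1, k + 1)]
                     for probe in probe_matrix.index}
    spot_ids = [sid for probe in probe_matrix.index
                for sid in replicate_map[probe]]
    base = np.repeat(probe_matrix.to_numpy(), k, axis=0)
    noise = rng.normal(0.0, config.replicate_sd, size=base.shape) \
        if config.replicate_sd > 0 else 0.0
    spot_matrix = pd.DataFrame(base + noise,
                               index=pd.Index(spot_ids, name="spot_id"),
                               columns=probe_matrix.columns)
    return spot_matrix, replicate_map, probe_matrix, annotation, truth


def config_from_mapping(mapping: Mapping) -> SyntheticConfig:
    """Build a config from a plain dict (e.g. parsed YAML), validating keys."""
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown synthetic config key(s): {sorted(unknown)}")
    kwargs = dict(mapping)
    if "survival_scale_by_group" in kwargs:
        kwargs["survival_scale_by_group"] = tuple(
            float(x) for x in kwargs["survival_scale_by_group"])
    return SyntheticConfig(**kwargs)
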