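"""Synthetic labelled datasets with the GC-asymmetry structure the encoder
targets.

Positives carry a sign-switching G-vs-C skew around the sequence centre
(G-enriched 5' half, C-enriched 3' half), mimicking the skew flip observed
around replication origins; negatives are skew-free. Both classes share the
same length distribution, overall GC content, and a mild A/T enrichment in
the middle third (AT-richness around origins is a compositional feature both
classes receive here, so that at skew magnitude s = 0 the two classes are
distributionally identical and the skew switch is the only class signal).

Per-position sampling for a sequence of length L with GC content g, skew s,
middle-third A/T enrichment e:

* outside the middle third: P(G) + P(C) = g; inside: g - e (A and T split
  the remainder equally);
* positives: P(G) = (gc_mass/2)(1+s), P(C) = (gc_mass/2)(1-s) in the 5'
  half, swapped in the 3' half; negatives: P(G) = P(C) = gc_mass/2.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import CvPlan, forest_pipeline, kfold_evaluate
from .features import PsekgccParams, encode_matrix
from .model import ForestConfig
from .seqio import DnaRecord, write_fasta, write_label_table

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults emulate compact yeast-like candidate regions: lengths uniform on
    [250, 1000] bp, GC content 0.38, skew magnitude 0.6, and a 0.1 A/T
    enrichment in the middle third.
    """

    n_pos: int
    n_neg: int
    length_range: tuple[int, int] = (250, 1000)
    gc_content: float = 0.38
    skew_magnitude: float = 0.6
    at_enrichment_mid: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must be in (0,1), got {self.gc_content}")
        if not 0.0 <= self.skew_magnitude <= 1.0:
            raise ValueError(f"skew magnitude must be in [0,1], got {self.skew_magnitude}")
        gc_mid = self.gc_content - self.at_enrichment_mid
        if gc_mid <= 0.0:
            raise ValueError(
                f"at_enrichment_mid={self.at_enrichment_mid} leaves no G/C mass "
                f"in the middle third (gc_content={self.gc_content})"
            )
        # all per-position probabilities must stay in [0, 1]
        if self.gc_content / 2 * (1 + self.skew_magnitude) > 1.0:
            raise ValueError("skewed G probability exceeds 1")


def _base_probabilities(L: int, skew: float, cfg: SyntheticConfig) -> np.ndarray:
    """(L, 4) per-position probabilities over A, C, G, T."""
    pos = np.arange(L)
    in_mid = (pos >= L / 3) & (pos < 2 * L / 3)
    gc_mass = np.where(in_mid, cfg.gc_content - cfg.at_enrichment_mid, cfg.gc_content)
    # sign-switching skew: +s in the 5' half, -s in the 3' half
    local_skew = np.where(pos < L / 2, skew, -skew)
    p = np.empty((L, 4))
    p[:, 2] = gc_mass / 2 * (1 + local_skew)  # G
    p[:, 1] = gc_mass / 2 * (1 - local_skew)  # C
    at_mass = 1.0 - gc_mass
    p[:, 0] = at_mass / 2  # A
    p[:, 3] = at_mass / 2  # T
    return p


def _sample_sequence(L: int, skew: float, cfg: SyntheticConfig, rng) -> str:
    p = _base_probabilities(L, skew, cfg)
    cum = np.cumsum(p, axis=1)
    u = rng.random(L)
    idx = (u[:, None] >= cum).sum(axis=1)
    return "".join(_BASES[idx])


def generate_dataset(config: SyntheticConfig) -> tuple[list[DnaRecord], np.ndarray]:
    """Generate labelled records (positives first). Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records: list[DnaRecord] = []
    labels: list[int] = []
    for i in range(config.n_pos):
        L = int(rng.integers(lo, hi + 1))
        records.append(
            DnaRecord(id=f"pos_{i:04d}",
                      sequence=_sample_sequence(L, config.skew_magnitude, config, rng))
        )
        labels.append(1)
    for i in range(config.n_neg):
        L = int(rng.integers(lo, hi + 1))
        records.append(
            DnaRecord(id=f"neg_{i:04d}",
                      sequence=_sample_sequence(L, 0.0, config, rng))
        )
        labels.append(0)
    return records, np.asarray(labels, dtype=int)


def write_dataset(
    records: Sequence[DnaRecord],
    labels: np.ndarray,
    fasta_path: str | Path,
    labels_path: str | Path,
) -> None:
    """FASTA plus the separate two-column (id, label) table."""
    write_fasta(records, fasta_path)
    write_label_table((r.id for r in records), labels, labels_path)


DEFAULT_SWEEP_PARAMS = PsekgccParams(epsilon=0.25, delta=0.75, k=3, lam=1, w=0.3)


def effect_size_sweep(
    s_values: Sequence[float],
    config: SyntheticConfig,
    params: PsekgccParams = DEFAULT_SWEEP_PARAMS,
    forest_config: ForestConfig | None = None,
    plan: CvPlan | None = None,
) -> pd.DataFrame:
    """5-fold CV AUC of a single PseKGCC forest at each skew magnitude.

    ``s_values`` must be sorted ascending; AUC is expected to rise with the
    effect size up to sampling noise. Returns a (s, auc) table.
    """
    if list(s_values) != sorted(s_values):
        raise ValueError("s_values must be sorted ascending")
    fc = forest_config or ForestConfig(n_trees=300)
    plan = plan or CvPlan(seed=config.seed)
    pipeline = forest_pipeline(fc)
    rows = []
    for s in s_values:
        cfg = SyntheticConfig(
            n_pos=config.n_pos, n_neg=config.n_neg,
            length_range=config.length_range, gc_content=config.gc_content,
            skew_magnitude=float(s), at_enrichment_mid=config.at_enrichment_mid,
            seed=config.seed,
        )
        records, labels = generate_dataset(cfg)
        X = encode_matrix(records, params).to_numpy()
        metrics, _ = kfold_evaluate(X, labels, pipeline, plan)
        rows.append({"s": float(s), "auc": metrics.auc})
    return pd.DataFrame(rows)


def read_config_file(path: str | Path) -> SyntheticConfig:
    """Parse a flat key=value file into a :class:`SyntheticConfig`."""
    values: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        values[key.strip()] = value.strip()
    kwargs: dict = {}
    for key in ("n_pos", "n_neg", "seed"):
        if key in values:
            kwargs[key] = int(values.pop(key))
    for key in ("gc_content", "skew_magnitude", "at_enrichment_mid"):
        if key in values:
            kwargs[key] = float(values.pop(key))
    if "length_range" in values:
        lo, hi = values.pop("length_range").split(",")
        kwargs["length_range"] = (int(lo), int(hi))
    if values:
        raise ValueError(f"unknown config keys {sorted(values)}")
    return SyntheticConfig(**kwargs)
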