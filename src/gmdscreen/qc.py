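"""Methylation probe quality control.

Three filtering rules are applied to an Infinium 450K-style beta matrix, in
the order used for reporting (the rules commute because probe medians are
always computed on the *original* detection p-value matrix):

1. individual beta-values with detection p >= 1e-3 are masked (set missing);
2. probes whose median detection p across samples is >= 1e-6 are dropped;
3. probes on the SNP-overlap mask list (hg19 masking recommendations) are
   dropped.

Both thresholds are inclusive (``>=``). Beta-values are never modified, only
masked or removed; missing values propagate downstream as pairwise-unavailable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np
import pandas as pd

DETECTION_ENTRY_P = 1e-3   # per-measurement mask threshold, inclusive
DETECTION_PROBE_P = 1e-6   # per-probe median threshold, inclusive

__all__ = [
    "BetaMatrix",
    "QcReport",
    "mask_low_confidence",
    "drop_failing_probes",
    "drop_snp_masked",
    "run_qc",
]


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with optional detection p-values.

    ``beta`` holds fractions in [0, 1] (NaN = missing); ``detection_p`` is
    aligned to ``beta`` when present.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("beta-values must lie in [0, 1]")
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValueError("detection_p must be aligned with beta")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            self.beta.copy(),
            None if self.detection_p is None else self.detection_p.copy(),
        )


@dataclass
class QcReport:
    n_input_probes: int
    n_betas_masked: int = 0
    n_probes_dropped_detection: int = 0
    n_probes_dropped_snp: int = 0
    n_output_probes: int = 0

    def validate(self) -> None:
        expected = (
            self.n_input_probes
            - self.n_probes_dropped_detection
            - self.n_probes_dropped_snp
        )
        if self.n_output_probes != expected:
            raise ValueError(
                f"inconsistent QC report: {self.n_output_probes} output probes, "
                f"expected {expected}"
            )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


def _require_detection(bm: BetaMatrix, step: str) -> pd.DataFrame:
    if bm.detection_p is None:
        raise ValueError(
            f"{step} requires detection p-values; none attached. "
            "Skip this step explicitly if the data carry no detection p-values."
        )
    return bm.detection_p


def mask_low_confidence(bm: BetaMatrix) -> tuple[BetaMatrix, int]:
    """Mask betas whose detection p >= 1e-3 (inclusive boundary).

    Returns the masked matrix and the number of newly masked entries.
    """
    detp = _require_detection(bm, "mask_low_confidence")
    fail = detp.to_numpy() >= DETECTION_ENTRY_P
    beta = bm.beta.to_numpy(dtype=float).copy()
    newly = int((fail & ~np.isnan(beta)).sum())
    beta[fail] = np.nan
    out = pd.DataFrame(beta, index=bm.beta.index, columns=bm.beta.columns)
    return BetaMatrix(out, detp.copy()), newly


def drop_failing_probes(bm: BetaMatrix) -> tuple[BetaMatrix, list[str]]:
    """Drop whole probes with median detection p across samples >= 1e-6.

    Medians are taken over the full detection matrix (including entries masked
    by :func:`mask_low_confidence`), so the two rules commute.
    """
    detp = _require_detection(bm, "drop_failing_probes")
    med = detp.median(axis=1)
    dropped = list(med.index[med >= DETECTION_PROBE_P])
    keep = med.index.difference(dropped, sort=False)
    out = BetaMatrix(bm.beta.loc[keep], detp.loc[keep])
    return out, dropped


def drop_snp_masked(
    bm: BetaMatrix, mask_list: Iterable[str]
) -> tuple[BetaMatrix, list[str]]:
    """Drop probes on the SNP-overlap mask list.

    Mask entries absent from the matrix are ignored (not an error).
    """
    mask = set(mask_list)
    dropped = [p for p in bm.probe_ids if p in mask]
    keep = bm.probe_ids.difference(dropped, sort=False)
    detp = None if bm.detection_p is None else bm.detection_p.loc[keep]
    return BetaMatrix(bm.beta.loc[keep], detp), dropped


def run_qc(
    bm: BetaMatrix, snp_mask: Iterable[str] = ()
) -> tuple[BetaMatrix, QcReport]:
    """Apply all three filtering rules and assemble a :class:`QcReport`.

    SNP-probe removal is counted after the detection-based probe drop, so the
    two drop counts are disjoint.
    """
    report = QcReport(n_input_probes=len(bm.probe_ids))
    bm, report.n_betas_masked = mask_low_confidence(bm)
    bm, dropped_det = drop_failing_probes(bm)
    report.n_probes_dropped_detection = len(dropped_det)
    bm, dropped_snp = drop_snp_masked(bm, snp_mask)
    report.n_probes_dropped_snp = len(dropped_snp)
    report.n_output_probes = len(bm.probe_ids)
    report.validate()
    return bm, report
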