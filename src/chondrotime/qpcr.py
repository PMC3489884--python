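"""Relative qPCR quantification by the 2^-ddCt method.

Threshold-cycle (Ct) triplicates are averaged per (target, sample); the
target's mean Ct is normalized against a housekeeping reference gene within
each sample (dCt), referenced to a calibrator sample (ddCt), and converted
to a linear fold change 2^-ddCt.  A base-10 log of the fold change is
reported alongside for plotting.  Amplification-efficiency correction is
deliberately out of scope: the method assumes near-perfect doubling per
cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrPlate", "mean_ct", "ddct_fold_change", "quantify", "read_plate"]


@dataclass(frozen=True)
class QpcrPlate:
    """Ct measurements plus the reference gene and calibrator sample.

    ``data`` has one row per well with columns ``target``, ``sample``,
    ``replicate`` and ``ct`` (an optional ``timepoint`` column is carried
    through untouched).  Every sample must include measurements of the
    reference gene, otherwise dCt is undefined.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator: str

    def __post_init__(self) -> None:
        required = {"target", "sample", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table lacks column(s) {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("all Ct values must be positive and finite")
        samples = set(self.data["sample"])
        with_ref = set(
            self.data.loc[self.data["target"] == self.reference_gene, "sample"]
        )
        lacking = sorted(samples - with_ref)
        if lacking:
            raise ValueError(
                f"sample(s) without reference-gene ({self.reference_gene!r}) "
                f"measurements: {lacking}"
            )
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not on plate")

    @property
    def targets(self) -> list[str]:
        seen = dict.fromkeys(self.data["target"])
        return [t for t in seen if t != self.reference_gene]

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))


def mean_ct(replicates) -> tuple[float, float]:
    """Arithmetic mean and SD (ddof=1; 0.0 for singletons) of replicate Cts."""
    values = np.asarray(list(replicates), dtype=float)
    if values.size == 0:
        raise ValueError("empty replicate set")
    if not np.isfinite(values).all():
        raise ValueError("non-finite Ct among replicates")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def _well_mean(plate: QpcrPlate, target: str, sample: str) -> float:
    rows = plate.data[
        (plate.data["target"] == target) & (plate.data["sample"] == sample)
    ]
    if rows.empty:
        raise ValueError(
            f"no Ct measurements for target {target!r} in sample {sample!r}"
        )
    return mean_ct(rows["ct"])[0]


def ddct_fold_change(
    plate: QpcrPlate,
    target: str,
    sample: str,
    reference_gene: str | None = None,
    calibrator: str | None = None,
) -> float:
    """Fold change 2^-ddCt of ``target`` in ``sample`` vs the calibrator.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt is the
    sample's dCt minus the calibrator's.  The calibrator itself therefore
    maps to a fold change of exactly 1.
    """
    reference_gene = reference_gene or plate.reference_gene
    calibrator = calibrator or plate.calibrator
    dct_sample = _well_mean(plate, target, sample) - _well_mean(
        plate, reference_gene, sample
    )
    dct_calibrator = _well_mean(plate, target, calibrator) - _well_mean(
        plate, reference_gene, calibrator
    )
    return float(2.0 ** -(dct_sample - dct_calibrator))


def quantify(
    plate: QpcrPlate,
    reference_gene: str | None = None,
    calibrator: str | None = None,
) -> pd.DataFrame:
    """Full-plate 2^-ddCt table, one row per (target, sample).

    Columns: ``mean_ct``, ``sd_ct``, ``delta_ct``, ``delta_delta_ct``,
    ``fold_change`` and ``log10_fold_change``.
    """
    reference_gene = reference_gene or plate.reference_gene
    calibrator = calibrator or plate.calibrator
    rows = []
    for target in plate.targets:
        dct_cal = _well_mean(plate, target, calibrator) - _well_mean(
            plate, reference_gene, calibrator
        )
        for sample in plate.samples:
            grp = plate.data[
                (plate.data["target"] == target)
                & (plate.data["sample"] == sample)
            ]
            if grp.empty:
                raise ValueError(
                    f"no Ct measurements for target {target!r} in sample {sample!r}"
                )
            m, sd = mean_ct(grp["ct"])
            dct = m - _well_mean(plate, reference_gene, sample)
            ddct = dct - dct_cal
            fc = float(2.0 ** -ddct)
            rows.append(
                {
                    "target": target,
                    "sample": sample,
                    "mean_ct": m,
                    "sd_ct": sd,
                    "delta_ct": dct,
                    "delta_delta_ct": ddct,
                    "fold_change": fc,
                    "log10_fold_change": float(np.log10(fc)),
                }
            )
    return pd.DataFrame(rows)


def read_plate(path, reference_gene: str, calibrator: str) -> QpcrPlate:
    """Read a well table (TSV: target, sample[, timepoint], replicate, ct)."""
    data = pd.read_csv(path, sep="\t")
    return QpcrPlate(
        data=data, reference_gene=reference_gene, calibrator=calibrator
    )
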