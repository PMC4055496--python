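"""Endpoint real-time PCR species calling.

Two species-specific TaqMan probes (cod, *Gadus morhua*; haddock,
*Melanogrammus aeglefinus*) are read on separate dye layers of a
96-well plate.  A well is positive on a dye when its endpoint (cycle
40) ΔRn exceeds the plate's no-template-control threshold for that dye:

    z*M = M + 3.89 * SD + C

where M and SD are the mean and standard deviation of the NTC endpoint
ΔRn values, 3.89 is the one-tailed normal quantile for 99.999%
confidence (stored as a constant, digit for digit), and C (default
0.3) is a fixed offset absorbing spectral bleed between dye layers.
The comparison is strictly "larger than": a tie with the threshold is
negative.  Thresholds are computed per plate and per dye layer, never
pooled across plates.

The two probe calls combine into one of four sample categories: COD,
HADDOCK, INCONCLUSIVE (both probes amplified) or NEGATIVE (neither).
NEGATIVE means "neither cod nor haddock", not assay failure.  Samples
on plates failing QC are marked UNRESOLVED rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import taxa

__all__ = [
    "Z_CONSTANT",
    "DEFAULT_C",
    "PlateData",
    "NtcStats",
    "DualCall",
    "PlateQC",
    "endpoint_delta_rn",
    "ntc_threshold",
    "call_probe",
    "call_sample",
    "validate_plate",
    "call_plates",
]

# One-tailed Z for 99.999% confidence, as printed in the threshold formula.
Z_CONSTANT = 3.89
# Spectral-bleed offset C.
DEFAULT_C = 0.3

N_CYCLES = 40
ROLES = frozenset({"NTC", "POS_COD", "POS_HAD", "SAMPLE"})
_POS_ROLE_FOR_DYE = {"COD": "POS_COD", "HAD": "POS_HAD"}


class PlateData:
    """ΔRn trajectories for one plate, long format.

    Columns: well, role, sample_id, dye, cycle (1..40), delta_rn.
    ``dye_targets`` maps each dye layer to the species its probe
    detects; it is configuration, not hard-coded, because the assay
    could be re-probed.
    """

    def __init__(
        self,
        plate_id: str,
        df: pd.DataFrame,
        dye_targets: Mapping[str, str] | None = None,
    ):
        self.plate_id = str(plate_id)
        self.dye_targets = dict(dye_targets or taxa.DYE_TARGETS)
        required = {"well", "role", "sample_id", "dye", "cycle", "delta_rn"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"plate {plate_id}: missing columns {sorted(missing)}")
        bad_roles = set(df["role"].unique()) - ROLES
        if bad_roles:
            raise ValueError(f"plate {plate_id}: unknown roles {sorted(bad_roles)}")
        counts = df.groupby(["well", "dye"], sort=False)["cycle"].count()
        if (counts != N_CYCLES).any():
            bad = counts[counts != N_CYCLES].index.tolist()[:5]
            raise ValueError(
                f"plate {plate_id}: trajectories without exactly {N_CYCLES} cycles: {bad}"
            )
        self.df = df
        self._endpoints = (
            df[df["cycle"] == N_CYCLES]
            .set_index(["well", "dye"])[["role", "sample_id", "delta_rn"]]
        )

    @property
    def dyes(self) -> list[str]:
        return sorted(self.df["dye"].unique())

    def wells(self, role: str | None = None) -> list[str]:
        sub = self.df if role is None else self.df[self.df["role"] == role]
        return sorted(sub["well"].unique())

    def ntc_endpoints(self, dye: str) -> np.ndarray:
        ep = self._endpoints
        sel = ep[(ep["role"] == "NTC") & (ep.index.get_level_values("dye") == dye)]
        return sel["delta_rn"].to_numpy()

    def endpoint_table(self) -> pd.DataFrame:
        """endpoint ΔRn per (well, dye) with role and sample linkage."""
        return self._endpoints.reset_index()

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "plate_id", self.plate_id)
        out.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, dye_targets: Mapping[str, str] | None = None) -> list["PlateData"]:
        df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=False)
        plates = []
        for plate_id, sub in df.groupby("plate_id", sort=True):
            plates.append(cls(plate_id, sub.drop(columns="plate_id").reset_index(drop=True), dye_targets))
        return plates


def endpoint_delta_rn(plate: PlateData, well: str, dye: str) -> float:
    """The cycle-40 ΔRn of a well/dye trajectory, exactly (no smoothing)."""
    try:
        return float(plate._endpoints.loc[(well, dye), "delta_rn"])
    except KeyError:
        raise KeyError(
            f"plate {plate.plate_id}: no cycle-{N_CYCLES} ΔRn for well {well!r}, dye {dye!r}"
        ) from None


@dataclass(frozen=True)
class NtcStats:
    """No-template-control statistics and the derived z*M threshold."""

    M: float
    SD: float
    n_ntc: int
    C: float = DEFAULT_C
    Z: float = Z_CONSTANT

    @property
    def zM(self) -> float:
        return self.M + self.Z * self.SD + self.C


def ntc_threshold(ntc_endpoints: Sequence[float], C: float = DEFAULT_C) -> NtcStats:
    """z*M = mean + 3.89*SD + C from NTC endpoint ΔRn values (one dye).

    The SD is the sample standard deviation (n-1 denominator, as a
    spreadsheet STDEV would give); at least two NTC endpoints are
    required for it to be defined.
    """
    values = np.asarray(list(ntc_endpoints), dtype=float)
    if values.size < 2:
        raise ValueError(f"need >= 2 NTC endpoints to define SD, got {values.size}")
    return NtcStats(M=float(values.mean()), SD=float(values.std(ddof=1)), n_ntc=int(values.size), C=C)


def call_probe(sample_endpoint: float, stats: NtcStats) -> bool:
    """True iff the endpoint is strictly larger than z*M (ties negative)."""
    return sample_endpoint > stats.zM


def call_sample(cod: bool, had: bool) -> "DualCall":
    """Combine the two probe booleans into the four-way category."""
    if cod and not had:
        call = "COD"
    elif had and not cod:
        call = "HADDOCK"
    elif cod and had:
        call = "INCONCLUSIVE"
    else:
        call = "NEGATIVE"
    return DualCall(cod_positive=cod, had_positive=had, call=call)


@dataclass(frozen=True)
class DualCall:
    cod_positive: bool
    had_positive: bool
    call: str
    sample_id: str | None = None


@dataclass
class PlateQC:
    """QC outcome for one plate; failure is a state, not an exception."""

    plate_id: str
    passed: bool
    n_ntc: int
    thresholds: dict[str, float]
    failures: list[str] = field(default_factory=list)


MIN_NTC_WELLS = 8


def validate_plate(plate: PlateData, C: float = DEFAULT_C) -> PlateQC:
    """Plate passes iff >= 8 NTC wells are present, every positive
    control exceeds its dye's threshold, and no NTC calls positive."""
    failures: list[str] = []
    ntc_wells = plate.wells("NTC")
    if len(ntc_wells) < MIN_NTC_WELLS:
        failures.append(f"only {len(ntc_wells)} NTC wells (need >= {MIN_NTC_WELLS})")

    thresholds: dict[str, float] = {}
    for dye in plate.dyes:
        try:
            stats = ntc_threshold(plate.ntc_endpoints(dye), C)
        except ValueError as exc:
            failures.append(f"dye {dye}: {exc}")
            continue
        thresholds[dye] = stats.zM
        pos_role = _POS_ROLE_FOR_DYE.get(dye)
        if pos_role is not None:
            pos_wells = plate.wells(pos_role)
            if len(pos_wells) < 2:
                failures.append(f"dye {dye}: {len(pos_wells)} positive controls (need 2)")
            for well in pos_wells:
                if not call_probe(endpoint_delta_rn(plate, well, dye), stats):
                    failures.append(f"dye {dye}: positive control {well} below z*M")
        for well in ntc_wells:
            if call_probe(endpoint_delta_rn(plate, well, dye), stats):
                failures.append(f"dye {dye}: NTC {well} above z*M")

    return PlateQC(
        plate_id=plate.plate_id,
        passed=not failures,
        n_ntc=len(ntc_wells),
        thresholds=thresholds,
        failures=failures,
    )


def call_plates(
    plates: Iterable[PlateData], C: float = DEFAULT_C
) -> tuple[pd.DataFrame, list[PlateQC]]:
    """Per-sample dual-probe calls over a set of plates.

    Returns a frame with columns sample_id, plate_id, cod_positive,
    had_positive, call, resolved.  Samples on plates failing QC keep
    call "UNRESOLVED" with resolved=False.
    """
    rows = []
    reports = []
    for plate in plates:
        qc = validate_plate(plate, C)
        reports.append(qc)
        stats = {dye: ntc_threshold(plate.ntc_endpoints(dye), C) for dye in plate.dyes}
        ep = plate.endpoint_table()
        samples = ep[ep["role"] == "SAMPLE"]
        for sample_id, sub in samples.groupby("sample_id", sort=True):
            by_dye = dict(zip(sub["dye"], sub["delta_rn"]))
            cod = call_probe(by_dye.get("COD", float("-inf")), stats["COD"])
            had = call_probe(by_dye.get("HAD", float("-inf")), stats["HAD"])
            dual = call_sample(cod, had)
            rows.append(
                {
                    "sample_id": sample_id,
                    "plate_id": plate.plate_id,
                    "cod_positive": cod,
                    "had_positive": had,
                    "call": dual.call if qc.passed else "UNRESOLVED",
                    "resolved": qc.passed,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "plate_id", "cod_positive", "had_positive", "call", "resolved"]), reports
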