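"""Chemical-activity dosimetry for hydrophobic contaminant mixtures.

Chemical activity expresses the effective (freely dissolved) concentration
of a hydrophobic organic chemical relative to its subcooled liquid
solubility.  For a PAH congener measured in algal tissue,

    C_free = C_algae / K_OC        (mg L-1)
    a      = C_free / S_L          (unitless)

where C_algae is the lipid-normalized tissue concentration (mg kg-1),
K_OC the organic carbon-water partition coefficient (L kg-1) and S_L the
subcooled liquid solubility (mg L-1).  Activities are additive across the
congeners of a mixture for baseline (narcotic) toxicity, so the total
mixture activity is the sum of per-congener activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CongenerRecord",
    "ActivityResult",
    "free_concentration",
    "activity",
    "total_activity",
    "read_congener_table",
]

#: Activities above this value indicate super-saturation and are flagged.
SATURATION_LIMIT = 1.0


@dataclass(frozen=True)
class CongenerRecord:
    """Per-congener dosimetry parameters.

    c_algae: tissue concentration, mg per kg lipid; koc: organic
    carbon-water partition coefficient, L per kg; sl: subcooled liquid
    solubility, mg per L.
    """

    name: str
    c_algae: float
    koc: float
    sl: float

    def __post_init__(self) -> None:
        if self.koc <= 0:
            raise ValueError(f"{self.name}: koc must be positive, got {self.koc}")
        if self.sl <= 0:
            raise ValueError(f"{self.name}: sl must be positive, got {self.sl}")
        if self.c_algae < 0:
            raise ValueError(f"{self.name}: c_algae must be non-negative, got {self.c_algae}")


@dataclass(frozen=True)
class ActivityResult:
    """Per-congener free concentrations/activities and the mixture total."""

    per_congener: dict[str, tuple[float, float]]
    total_activity: float
    saturated: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"name": name, "c_free": cf, "activity": a, "saturated": name in self.saturated}
            for name, (cf, a) in self.per_congener.items()
        ]
        return pd.DataFrame(rows)


def free_concentration(c_algae: float, koc: float) -> float:
    """Freely dissolved concentration (mg L-1) from tissue concentration."""
    if koc <= 0:
        raise ValueError(f"koc must be positive, got {koc}")
    if c_algae < 0:
        raise ValueError(f"c_algae must be non-negative, got {c_algae}")
    return c_algae / koc


def activity(c_free: float, sl: float) -> float:
    """Chemical activity (unitless) of one congener.

    Values above 1 indicate super-saturation; they are returned as-is (the
    caller may inspect :func:`total_activity`'s ``saturated`` flags).
    """
    if sl <= 0:
        raise ValueError(f"sl must be positive, got {sl}")
    if c_free < 0:
        raise ValueError(f"c_free must be non-negative, got {c_free}")
    return c_free / sl


def total_activity(records: list[CongenerRecord]) -> ActivityResult:
    """Total mixture chemical activity: the sum over congeners."""
    if not records:
        raise ValueError("congener list is empty")
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate congener names: {dupes}")
    per: dict[str, tuple[float, float]] = {}
    saturated: list[str] = []
    for rec in records:
        c_free = free_concentration(rec.c_algae, rec.koc)
        a = activity(c_free, rec.sl)
        if a > SATURATION_LIMIT:
            saturated.append(rec.name)
        per[rec.name] = (c_free, a)
    return ActivityResult(
        per_congener=per,
        total_activity=sum(a for _, a in per.values()),
        saturated=tuple(saturated),
    )


def read_congener_table(path: str) -> list[CongenerRecord]:
    """Read a congener parameter CSV.

    Required columns: ``name``, ``c_algae`` and either natural-scale
    ``koc``/``sl`` or log10-scale ``log_koc``/``log_sl`` (converted at
    parse time; literature tables mix conventions).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "name" not in cols or "c_algae" not in cols:
        raise ValueError("congener table needs 'name' and 'c_algae' columns")

    def _get(row: pd.Series, natural: str, log10: str) -> float:
        if natural in cols and pd.notna(row.get(natural)):
            return float(row[natural])
        if log10 in cols and pd.notna(row.get(log10)):
            return float(10.0 ** row[log10])
        raise ValueError(f"row {row['name']!r}: neither {natural} nor {log10} present")

    return [
        CongenerRecord(
            name=str(row["name"]),
            c_algae=float(row["c_algae"]),
            koc=_get(row, "koc", "log_koc"),
            sl=_get(row, "sl", "log_sl"),
        )
        for _, row in df.iterrows()
    ]
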