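"""emPAI-based quantification of extracellular-matrix ligands.

Label-free shotgun proteomics of a fractionated ECM extraction (NaCl, SDS,
GnHCl fractions; control vs treated livers) reports one exponentially
modified protein abundance index (emPAI) per protein, fraction and group.
emPAI is approximately proportional to molar protein abundance, so after
weighting by the mass concentration loaded on the instrument and dividing by
the molecular weight, it serves as a proteomic ruler: an absolute molar
concentration estimate for every identified ECM protein.  Those molar
concentrations are the ligand pools that drive the receptor-binding models
in :mod:`ecmbind.kinetics`.

The module ingests delimited exports (one row per protein/fraction/group),
pools fractions, converts emPAI to µM, computes treatment-over-control log2
fold changes with a zero floor, and classifies each protein as unique to one
group or shared.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("ecmbind.proteome")

#: Mass concentration loaded on the LC column for every fraction (µg/µL).
DEFAULT_LOADING_UG_PER_UL = 0.25
#: Zero floor applied to molar concentrations (µM) before log2 fold change.
DEFAULT_LOG2FC_FLOOR_UM = 1e-5
#: Reporting tolerance used to flag printed fold changes that disagree with
#: the printed concentration cells beyond last-digit rounding.
LOG2FC_REPORT_TOL = 0.02

COMBINED = "combined"
REQUIRED_COLUMNS = ("protein_id", "mw_kda", "group", "fraction", "empai")

UNIQUE_TREATMENT = "unique_treatment"
UNIQUE_CONTROL = "unique_control"
SHARED = "shared"


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """One protein's emPAI score within a treatment group and fraction.

    Parameters
    ----------
    protein_id : str
        Protein identifier (gene/protein name as exported).
    mw_kda : float
        Molecular weight in kDa, strictly positive.
    group : str
        Treatment label, e.g. ``control`` or ``ccl4``.
    fraction : str
        Extraction-fraction label (``nacl``/``sds``/``gnhcl``) or
        ``combined`` for pre-pooled tables.
    empai : float
        Dimensionless emPAI score, non-negative.
    go_accession : str, optional
        Accession from the gene-ontology annotation, if exported.
    """

    protein_id: str
    mw_kda: float
    group: str
    fraction: str
    empai: float
    go_accession: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not (self.mw_kda > 0):
            raise ValidationError(
                f"{self.protein_id}: molecular weight must be > 0 kDa, got {self.mw_kda}"
            )
        if not (self.empai >= 0):
            raise ValidationError(
                f"{self.protein_id}: emPAI must be >= 0, got {self.empai}"
            )


@dataclasses.dataclass
class AbundanceTable:
    """Per-protein molar concentrations for two groups plus derived columns.

    ``data`` has one row per protein with columns ``protein_id``,
    ``go_accession``, ``mw_kda``, ``conc_control_uM``, ``conc_treatment_uM``,
    ``log2fc`` and ``presence_class``.  Proteins with zero abundance in both
    groups are excluded (and logged) before classification.
    """

    data: pd.DataFrame
    control_group: str = "control"
    treatment_group: str = "ccl4"
    loading_ug_per_ul: float = DEFAULT_LOADING_UG_PER_UL
    floor_um: float = DEFAULT_LOG2FC_FLOOR_UM

    def __post_init__(self) -> None:
        if (self.data["conc_control_uM"] < 0).any() or (
            self.data["conc_treatment_uM"] < 0
        ).any():
            raise ValidationError("molar concentrations must be >= 0")

    @classmethod
    def from_concentrations(
        cls,
        frame: pd.DataFrame,
        control_group: str = "control",
        treatment_group: str = "ccl4",
        floor_um: float = DEFAULT_LOG2FC_FLOOR_UM,
        **kwargs,
    ) -> "AbundanceTable":
        """Build a table directly from per-group µM columns (used when the
        upstream pipeline already reports concentrations)."""
        df = frame.copy()
        df["log2fc"] = log2_fold_change(
            df["conc_control_uM"].to_numpy(),
            df["conc_treatment_uM"].to_numpy(),
            floor=floor_um,
        )
        table = cls(
            data=df,
            control_group=control_group,
            treatment_group=treatment_group,
            floor_um=floor_um,
            **kwargs,
        )
        _attach_presence(table)
        return table

    def write(self, path: str | Path, sep: str = "\t") -> None:
        """Write the table (µM per group, log2FC, presence class)."""
        self.data.to_csv(path, sep=sep, index=False)


def _delimiter(dialect: str) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    if len(dialect) == 1:
        return dialect
    raise ConfigurationError(f"unknown dialect {dialect!r}; use 'tsv', 'csv' or a single character")


def read_protein_table(path: str | Path, dialect: str = "tsv") -> list[ProteinRecord]:
    """Parse a delimited protein-quantification export.

    The file must carry a header row with at least the columns
    ``protein_id, mw_kda, group, fraction, empai`` (``go_accession`` is
    optional); lines starting with ``#`` are metadata comments.  Malformed
    numeric cells are reported with their file line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    records: list[ProteinRecord] = []
    errors: list[str] = []
    # +2: header line plus 1-based indexing. Comment lines above the header
    # would shift this, which is acceptable for error reporting.
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        try:
            mw = float(row["mw_kda"])
            empai = float(row["empai"])
        except (TypeError, ValueError):
            errors.append(f"row {line_no}: malformed numeric cell "
                          f"(mw_kda={row['mw_kda']!r}, empai={row['empai']!r})")
            continue
        go = row.get("go_accession")
        try:
            records.append(
                ProteinRecord(
                    protein_id=str(row["protein_id"]),
                    mw_kda=mw,
                    group=str(row["group"]),
                    fraction=str(row["fraction"]),
                    empai=empai,
                    go_accession=None if pd.isna(go) else str(go),
                )
            )
        except ValidationError as exc:
            errors.append(f"row {line_no}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    _check_unique(records)
    return records


def _check_unique(records: Sequence[ProteinRecord]) -> None:
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.protein_id, rec.group, rec.fraction)
        if key in seen:
            raise ValidationError(
                f"duplicate (protein, group, fraction) entry: {key}"
            )
        seen.add(key)


def records_to_frame(records: Iterable[ProteinRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def combine_fractions(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Pool per-fraction emPAI scores into one combined score per protein.

    Mirrors the MudPIT-style recombination of fraction-level search results:
    the combined emPAI is the sum over fractions, an additive approximation
    of pooling the observable peptide evidence.  Pooling is done per
    (group, protein); already-combined records pass through.
    """
    _check_unique(records)
    combined: dict[tuple[str, str], dict] = {}
    for rec in records:
        key = (rec.group, rec.protein_id)
        if key not in combined:
            combined[key] = {
                "mw_kda": rec.mw_kda,
                "go_accession": rec.go_accession,
                "empai": 0.0,
            }
        elif not math.isclose(combined[key]["mw_kda"], rec.mw_kda, rel_tol=1e-9):
            raise ValidationError(
                f"{rec.protein_id} ({rec.group}): inconsistent molecular weight "
                f"across fractions ({combined[key]['mw_kda']} vs {rec.mw_kda} kDa)"
            )
        combined[key]["empai"] += rec.empai
    return [
        ProteinRecord(
            protein_id=pid,
            mw_kda=v["mw_kda"],
            group=group,
            fraction=COMBINED,
            empai=v["empai"],
            go_accession=v["go_accession"],
        )
        for (group, pid), v in combined.items()
    ]


def empai_to_molar(
    empai, mw_kda, loading: float = DEFAULT_LOADING_UG_PER_UL
):
    """Convert an emPAI score to a molar concentration in µM.

    The score is read as a fraction of the loaded mass concentration
    (``loading`` µg/µL ≡ g/L), then divided by the molecular weight:

        µM = emPAI × loading [g/L] / (mw [kDa] × 1000 [g/mol]) × 1e6

    which simplifies to ``empai * loading * 1000 / mw_kda``.  Linear in both
    emPAI and loading; inversely proportional to molecular weight.
    """
    mw = np.asarray(mw_kda, dtype=float)
    if np.any(mw <= 0):
        raise ValidationError(f"molecular weight must be > 0 kDa, got {mw_kda}")
    if not loading > 0:
        raise ValidationError(f"loading must be > 0 µg/µL, got {loading}")
    e = np.asarray(empai, dtype=float)
    if np.any(e < 0):
        raise ValidationError(f"emPAI must be >= 0, got {empai}")
    out = e * loading * 1000.0 / mw
    return out if out.ndim else float(out)


def molar_to_empai(
    molar_um, mw_kda, loading: float = DEFAULT_LOADING_UG_PER_UL
):
    """Algebraic inverse of :func:`empai_to_molar` (µM → emPAI)."""
    mw = np.asarray(mw_kda, dtype=float)
    out = np.asarray(molar_um, dtype=float) * mw / (loading * 1000.0)
    return out if out.ndim else float(out)


def log2_fold_change(
    conc_control, conc_treatment, floor: float = DEFAULT_LOG2FC_FLOOR_UM
):
    """Treatment-over-control log2 ratio with a zero floor.

    Both concentrations (µM) are floored at ``floor`` (default 1e-5 µM, the
    substitution applied to zero cells) so that absent proteins yield a
    large-but-finite fold change rather than ±inf.
    """
    if not floor > 0:
        raise ConfigurationError(f"log2fc floor must be > 0, got {floor}")
    a = np.maximum(np.asarray(conc_control, dtype=float), floor)
    b = np.maximum(np.asarray(conc_treatment, dtype=float), floor)
    if np.any(np.asarray(conc_control) < 0) or np.any(np.asarray(conc_treatment) < 0):
        raise ValidationError("concentrations must be >= 0")
    out = np.log2(b / a)
    return out if out.ndim else float(out)


def quantify(
    records: Sequence[ProteinRecord],
    control_group: str = "control",
    treatment_group: str = "ccl4",
    loading: float = DEFAULT_LOADING_UG_PER_UL,
    floor: float = DEFAULT_LOG2FC_FLOOR_UM,
) -> AbundanceTable:
    """Full quantification: pool fractions, convert to µM, derive log2FC and
    presence classes for a two-group experiment."""
    groups = {r.group for r in records}
    unknown = groups - {control_group, treatment_group}
    if unknown:
        raise ConfigurationError(
            f"records contain group(s) {sorted(unknown)} not matching "
            f"control={control_group!r}/treatment={treatment_group!r}"
        )
    pooled = combine_fractions(records)
    rows: dict[str, dict] = {}
    for rec in pooled:
        row = rows.setdefault(
            rec.protein_id,
            {
                "protein_id": rec.protein_id,
                "go_accession": rec.go_accession,
                "mw_kda": rec.mw_kda,
                "conc_control_uM": 0.0,
                "conc_treatment_uM": 0.0,
            },
        )
        conc = empai_to_molar(rec.empai, rec.mw_kda, loading)
        if rec.group == control_group:
            row["conc_control_uM"] = conc
        else:
            row["conc_treatment_uM"] = conc
    frame = pd.DataFrame(list(rows.values()))
    return AbundanceTable.from_concentrations(
        frame,
        control_group=control_group,
        treatment_group=treatment_group,
        floor_um=floor,
        loading_ug_per_ul=loading,
    )


def _attach_presence(table: AbundanceTable) -> None:
    df = table.data
    ctrl = df["conc_control_uM"].to_numpy()
    trt = df["conc_treatment_uM"].to_numpy()
    both_zero = (ctrl == 0) & (trt == 0)
    if both_zero.any():
        dropped = df.loc[both_zero, "protein_id"].tolist()
        logger.warning(
            "excluding %d protein(s) with zero abundance in both groups: %s",
            len(dropped), dropped,
        )
        df = df.loc[~both_zero].reset_index(drop=True)
        ctrl = df["conc_control_uM"].to_numpy()
        trt = df["conc_treatment_uM"].to_numpy()
    cls = np.where(
        ctrl == 0, UNIQUE_TREATMENT, np.where(trt == 0, UNIQUE_CONTROL, SHARED)
    )
    df = df.assign(presence_class=cls)
    table.data = df


def classify_presence(table: AbundanceTable) -> dict[str, int]:
    """Count proteins unique to either group or shared.

    Counts partition the set of proteins with any nonzero abundance:
    ``unique_treatment + unique_control + shared == len(table.data)``.
    """
    counts = table.data["presence_class"].value_counts().to_dict()
    return {
        UNIQUE_TREATMENT: int(counts.get(UNIQUE_TREATMENT, 0)),
        UNIQUE_CONTROL: int(counts.get(UNIQUE_CONTROL, 0)),
        SHARED: int(counts.get(SHARED, 0)),
    }
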