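"""Data model and CSV I/O for paired MRM-MS cohorts.

The pipeline operates on two containers:

``PeptideTable``
    Per-sample endogenous/heavy-standard ratios for each measured peptide,
    together with per-peptide QC metadata (median instrument response,
    recoveries of the spiked heavy standards) and per-sample clinical
    metadata (patient, disease state, cohort, timepoint).

``ProteinMatrix``
    Log2 protein levels (one representative peptide per protein) by sample,
    carrying the same sample metadata plus the provenance of the
    representative-peptide choice.

Missing measurements (below the limit of detection) are NaN in memory, an
empty cell or ``NA`` on disk — never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EXACERBATION = "exacerbation"
CONVALESCENT = "convalescent"
STATES = (EXACERBATION, CONVALESCENT)

#: column-name -> role mapping used by default when reading peptide CSVs.
DEFAULT_DIALECT = {
    "peptide_id": "peptide",
    "protein_id": "protein",
    "uniprot_id": "uniprot",
    "gene_symbol": "gene",
    "median_response": "median_response",
    "standard_recoveries": "standard_recoveries",
    "recovery_sep": ";",
    "na_values": ["", "NA"],
}

SAMPLE_COLUMNS = ["patient_id", "state", "cohort", "timepoint_days"]


class ValidationError(ValueError):
    """Raised when a table violates one of its structural invariants."""


@dataclass
class PeptideTable:
    """Peptide-level ratios plus QC and sample metadata.

    Parameters
    ----------
    ratios : DataFrame, peptides x samples
        Endogenous/heavy-standard ratios; NaN marks a missing (below-LOD)
        measurement.
    peptide_meta : DataFrame indexed by peptide_id
        Columns ``protein_id``, ``uniprot_id``, ``gene_symbol``,
        ``median_response`` and ``standard_recoveries`` (list of percent
        recoveries, nominal window 80-120).
    samples : DataFrame indexed by sample_id
        Columns ``patient_id``, ``state`` (one of :data:`STATES`),
        ``cohort``, ``timepoint_days``.
    """

    ratios: pd.DataFrame
    peptide_meta: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.ratios.index.name = "peptide_id"
        self.ratios.columns.name = "sample_id"
        self.samples.index.name = "sample_id"
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.ratios.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate peptide_id(s): {dups}")
        if not idx.equals(self.peptide_meta.index):
            raise ValidationError("ratios and peptide_meta indexes differ")
        unknown = [c for c in self.ratios.columns if c not in self.samples.index]
        if unknown:
            raise ValidationError(
                f"sample column(s) with no sample metadata: {unknown}"
            )
        vals = self.ratios.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValidationError("negative ratio values present")
        if (self.peptide_meta["protein_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty protein_id present")
        bad_state = set(self.samples["state"]) - set(STATES) - {"stable"}
        if bad_state:
            raise ValidationError(f"unknown sample state(s): {sorted(bad_state)}")
        key = self.samples[["patient_id", "state", "timepoint_days"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].to_records(index=True)
            raise ValidationError(
                f"duplicate (patient_id, state, timepoint_days): {list(dup)}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_peptides(self) -> int:
        return self.ratios.shape[0]

    @property
    def n_samples(self) -> int:
        return self.ratios.shape[1]

    def subset_peptides(self, peptide_ids) -> "PeptideTable":
        return PeptideTable(
            ratios=self.ratios.loc[peptide_ids].copy(),
            peptide_meta=self.peptide_meta.loc[peptide_ids].copy(),
            samples=self.samples.copy(),
        )

    def copy(self) -> "PeptideTable":
        return self.subset_peptides(self.ratios.index)


@dataclass
class ProteinMatrix:
    """Log2 protein levels by sample with representative-peptide provenance."""

    values: pd.DataFrame  # proteins x samples, log2 scale
    samples: pd.DataFrame  # indexed by sample_id
    provenance: pd.DataFrame | None = None  # indexed by protein_id

    def __post_init__(self) -> None:
        self.values.index.name = "protein_id"
        self.values.columns.name = "sample_id"
        self.samples.index.name = "sample_id"
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate protein rows")
        unknown = [c for c in self.values.columns if c not in self.samples.index]
        if unknown:
            raise ValidationError(
                f"sample column(s) with no sample metadata: {unknown}"
            )
        if self.values.size and self.values.isna().any().any():
            raise ValidationError("protein matrix contains missing values")
        if self.provenance is not None and len(self.provenance):
            if not self.provenance.index.equals(self.values.index):
                raise ValidationError("provenance index does not match proteins")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    def states(self) -> pd.Series:
        """State label per sample, aligned to the matrix columns."""
        return self.samples.loc[self.values.columns, "state"]

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            samples=self.samples.copy(),
            provenance=None if self.provenance is None else self.provenance.copy(),
        )


# ---------------------------------------------------------------------------
# dialect handling


def load_dialect(path=None) -> dict:
    """Merge a YAML dialect file (column-name -> role overrides) with defaults."""
    dialect = dict(DEFAULT_DIALECT)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        dialect.update(user)
    return dialect


def _parse_recoveries(cell, sep: str) -> list[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return [float(x) for x in str(cell).split(sep) if x != ""]


# ---------------------------------------------------------------------------
# PeptideTable I/O


def read_sample_info(path) -> pd.DataFrame:
    """Read the sample-metadata sidecar CSV (sample_id + clinical columns)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    missing = [c for c in ["sample_id", *SAMPLE_COLUMNS] if c not in df.columns]
    if missing:
        raise ValidationError(f"sample info file missing column(s): {missing}")
    df = df.set_index("sample_id")
    df["timepoint_days"] = df["timepoint_days"].astype(int)
    if (df["timepoint_days"] < 0).any():
        raise ValidationError("negative timepoint_days")
    return df


def read_peptide_table(path, samples, dialect=None) -> PeptideTable:
    """Read a wide peptide CSV into a :class:`PeptideTable`.

    ``samples`` is either a sample-info DataFrame or a path to the sidecar
    CSV. ``dialect`` maps on-disk column names to roles so supplementary
    files with unknown headers can be adapted without code changes; any
    column not claimed by the dialect is treated as a sample column.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    if not isinstance(samples, pd.DataFrame):
        samples = read_sample_info(samples)
    try:
        df = pd.read_csv(
            path,
            na_values=dialect["na_values"],
            keep_default_na=False,
            dtype={dialect["peptide_id"]: str},
        )
    except pd.errors.ParserError as exc:  # report the offending row
        raise ValidationError(f"malformed CSV {path}: {exc}") from exc

    roles = {
        dialect[k]: k
        for k in (
            "peptide_id",
            "protein_id",
            "uniprot_id",
            "gene_symbol",
            "median_response",
            "standard_recoveries",
        )
    }
    missing = [c for c in roles if c not in df.columns]
    if missing:
        raise ValidationError(f"peptide CSV missing column(s): {missing}")
    sample_cols = [c for c in df.columns if c not in roles]
    unknown = [c for c in sample_cols if c not in samples.index]
    if unknown:
        raise ValidationError(f"sample column(s) with no sample metadata: {unknown}")

    df = df.rename(columns=roles).set_index("peptide_id")
    meta = df[["protein_id", "uniprot_id", "gene_symbol", "median_response"]].copy()
    meta["median_response"] = meta["median_response"].astype(float)
    meta["standard_recoveries"] = [
        _parse_recoveries(c, dialect["recovery_sep"])
        for c in df["standard_recoveries"]
    ]
    ratios = df[sample_cols].astype(float)
    table = PeptideTable(
        ratios=ratios, peptide_meta=meta, samples=samples.loc[list(samples.index)]
    )
    logger.info(
        "read %d peptides x %d samples from %s",
        table.n_peptides,
        table.n_samples,
        path,
    )
    return table


def write_peptide_table(table: PeptideTable, path, samples_path=None, dialect=None):
    """Write a peptide CSV (and optionally the sample sidecar).

    Missing ratios are written as empty cells; read_peptide_table round-trips
    the output.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    sep = dialect["recovery_sep"]
    out = table.peptide_meta.copy()
    out["standard_recoveries"] = [
        sep.join(format(v, "g") for v in recs)
        for recs in out["standard_recoveries"]
    ]
    out = out.rename(
        columns={
            "protein_id": dialect["protein_id"],
            "uniprot_id": dialect["uniprot_id"],
            "gene_symbol": dialect["gene_symbol"],
            "median_response": dialect["median_response"],
            "standard_recoveries": dialect["standard_recoveries"],
        }
    )
    out = pd.concat([out, table.ratios], axis=1)
    out.index.name = dialect["peptide_id"]
    out.to_csv(path, na_rep="")
    if samples_path is not None:
        write_sample_info(table.samples, samples_path)


def write_sample_info(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path)


# ---------------------------------------------------------------------------
# ProteinMatrix I/O

_PROV_COL = "representative_peptide"


def write_protein_matrix(matrix: ProteinMatrix, path, samples_path) -> None:
    """Write proteins-by-samples CSV plus a sample state-label sidecar.

    Values round-trip bit-identically on their decimal representation
    (full repr precision). Raises on an empty matrix.
    """
    if matrix.values.size == 0:
        raise ValidationError("refusing to write an empty protein matrix")
    out = pd.DataFrame(index=matrix.values.index.rename("protein_id"))
    if matrix.provenance is not None:
        out[_PROV_COL] = matrix.provenance["peptide_id"].values
    out = pd.concat([out, matrix.values.set_axis(out.index, axis=0)], axis=1)
    out.to_csv(path, float_format=None)
    write_sample_info(matrix.samples, samples_path)


def read_protein_matrix(path, samples) -> ProteinMatrix:
    """Read a protein matrix CSV written by :func:`write_protein_matrix`."""
    if not isinstance(samples, pd.DataFrame):
        samples = read_sample_info(samples)
    df = pd.read_csv(path, dtype={"protein_id": str}).set_index("protein_id")
    prov = None
    if _PROV_COL in df.columns:
        prov = pd.DataFrame({"peptide_id": df.pop(_PROV_COL)})
    values = df.astype(float)
    matrix = ProteinMatrix(values=values, samples=samples, provenance=prov)
    logger.info(
        "read %d proteins x %d samples from %s",
        values.shape[0],
        values.shape[1],
        path,
    )
    return matrix
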