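"""Ct-table data model, I/O and transformation to relative quantities.

The central object is :class:`CtMatrix`: raw or replicate-collapsed cycle-threshold
(Ct) values for a panel of candidate reference genes, rows = genes, columns =
samples, with per-sample annotations (group/tissue, treatment, biological and
technical replicate ids).  Ct values are PCR cycle numbers, typically in the
10–40 range; a lower Ct means more abundant transcript.  Missing measurements
are carried as NaN, never as silent zeros.

Transformations:

* technical-replicate collapsing (arithmetic mean of non-missing replicate Cts),
* efficiency-corrected conversion to relative quantities
  ``q = (1 + E)^(Ct_min - Ct)`` with the per-gene minimum Ct as calibrator,
* per-sample normalization factors as geometric means of selected genes.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: advisory sanity bounds for Ct values, in cycles
CT_WARN_BOUNDS = (10.0, 40.0)

ANNOTATION_COLUMNS = ["group", "treatment", "biological_replicate", "technical_replicate"]
LONG_COLUMNS = ["gene", "sample", "group", "treatment", "bio_rep", "tech_rep", "ct"]


class CtDataError(ValueError):
    """Invalid Ct table input (duplicate pairs, missing annotations, bad values)."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Identity of one RT-qPCR well/sample.

    ``group`` is the biological stratum (tissue in the motivating study design),
    ``treatment`` the experimental condition; both must be non-empty.
    ``technical_replicate`` 0 denotes a replicate-collapsed pseudo-sample.
    """

    sample_id: str
    group: str
    treatment: str
    biological_replicate: int
    technical_replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise CtDataError("sample_id must be non-empty")
        if not self.group or not self.treatment:
            raise CtDataError(
                f"sample {self.sample_id!r}: group and treatment must be non-empty"
            )


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-gene PCR amplification efficiency.

    ``efficiency`` E is the per-cycle gain minus one (E = 1 is perfect
    doubling); when derived from a 10-fold dilution standard curve,
    ``E = 10**(-1/slope) - 1`` with ``slope`` in Ct per log10 dilution
    (necessarily negative).
    """

    gene: str
    efficiency: float
    slope: float | None = None

    def __post_init__(self) -> None:
        if self.efficiency <= 0:
            raise CtDataError(f"gene {self.gene!r}: efficiency must be > 0")
        if self.slope is not None:
            expected = efficiency_from_slope(self.slope)
            if not math.isclose(expected, self.efficiency, rel_tol=1e-3):
                raise CtDataError(
                    f"gene {self.gene!r}: efficiency {self.efficiency:.5f} inconsistent "
                    f"with slope {self.slope:.5f} (implies {expected:.5f})"
                )
        if self.efficiency > 1.5:
            warnings.warn(
                f"gene {self.gene!r}: efficiency {self.efficiency:.3f} exceeds 1.5 "
                "(>150% per-cycle gain is physically implausible)",
                stacklevel=2,
            )


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: ``10**(-1/slope) - 1``.

    A dilution-series standard curve plots Ct against log10 template amount and
    must have negative slope; ``slope = -1/log10(2) ≈ -3.32`` corresponds to
    perfect doubling (E = 1).
    """
    if not np.isfinite(slope) or slope >= 0:
        raise CtDataError(f"standard-curve slope must be finite and negative, got {slope!r}")
    return 10.0 ** (-1.0 / slope) - 1.0


class _GeneSampleMatrix:
    """Shared container: genes × samples value matrix plus sample annotations."""

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleAnnotation]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CtDataError(f"duplicate sample ids: {dup}")
        if list(values.columns) != ids:
            raise CtDataError("value columns must match sample annotations in order")
        if values.index.duplicated().any():
            dup = sorted(values.index[values.index.duplicated()].unique())
            raise CtDataError(f"duplicate gene ids: {dup}")
        self.values = values.astype(float)
        self.samples = samples
        self._by_id = {s.sample_id: s for s in samples}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def annotation(self, sample_id: str) -> SampleAnnotation:
        return self._by_id[sample_id]

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [s.group for s in self.samples],
                "treatment": [s.treatment for s in self.samples],
                "biological_replicate": [s.biological_replicate for s in self.samples],
                "technical_replicate": [s.technical_replicate for s in self.samples],
            },
            index=pd.Index(self.sample_ids, name="sample"),
        )

    def subset_samples(self, sample_ids: Sequence[str]):
        anns = [self._by_id[i] for i in sample_ids]
        return type(self)(self.values[list(sample_ids)], anns)

    def subset_genes(self, genes: Sequence[str]):
        return type(self)(self.values.loc[list(genes)], self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class CtMatrix(_GeneSampleMatrix):
    """Raw or replicate-collapsed Ct values (cycles), genes × samples.

    Non-missing entries must be finite and positive; values outside the
    advisory [10, 40] cycle window trigger a warning, not an error.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleAnnotation]):
        super().__init__(values, samples)
        v = self.values.to_numpy()
        finite = np.isfinite(v)
        if np.any(finite & (v <= 0)):
            raise CtDataError("Ct values must be > 0")
        if np.any(~finite & ~np.isnan(v)):
            raise CtDataError("Ct values must be finite or NaN")
        lo, hi = CT_WARN_BOUNDS
        n_odd = int(np.sum(finite & ((v < lo) | (v > hi))))
        if n_odd:
            warnings.warn(
                f"{n_odd} Ct value(s) outside the advisory [{lo:g}, {hi:g}] cycle range",
                stacklevel=2,
            )

    def complete_genes(self) -> list[str]:
        """Genes with no missing Ct in any sample."""
        return list(self.values.index[~self.values.isna().any(axis=1)])


class QuantityMatrix(_GeneSampleMatrix):
    """Efficiency-corrected relative expression quantities (dimensionless, > 0).

    Under the default per-gene-minimum-Ct calibrator every gene's maximum
    quantity is exactly 1.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleAnnotation],
        metadata: Mapping[str, object] | None = None,
    ):
        super().__init__(values, samples)
        v = self.values.to_numpy()
        if np.any(np.isfinite(v) & (v <= 0)):
            raise CtDataError("relative quantities must be > 0")
        self.metadata = dict(metadata or {})

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantityMatrix":
        anns = [self._by_id[i] for i in sample_ids]
        return QuantityMatrix(self.values[list(sample_ids)], anns, self.metadata)

    def subset_genes(self, genes: Sequence[str]) -> "QuantityMatrix":
        return QuantityMatrix(self.values.loc[list(genes)], self.samples, self.metadata)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_ct_cell(raw: object) -> float:
    """Parse one Ct cell; anything unparseable becomes NaN (flagged missing)."""
    if raw is None:
        return math.nan
    if isinstance(raw, (int, float)):
        return float(raw)
    s = str(raw).strip()
    if not s or s.upper() in {"NA", "NAN", "N/A", "NULL", "MISSING", "."}:
        return math.nan
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable Ct cell %r flagged as missing", raw)
        return math.nan


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)


def read_ct_table(
    path,
    dialect: str = "long",
    annotations=None,
) -> CtMatrix:
    """Read a Ct table from CSV.

    ``dialect='long'``: columns ``gene,sample,group,treatment,bio_rep,tech_rep,ct``.
    ``dialect='wide'``: first column the gene id, remaining columns sample ids;
    a sidecar annotation table (``annotations`` path or DataFrame) with columns
    ``sample,group,treatment,bio_rep,tech_rep`` is then required.

    Lines starting with ``#`` are metadata comments and ignored.  A duplicate
    (gene, sample) pair or a sample column without an annotation row is a hard
    error; an unparseable Ct cell becomes a flagged missing value.
    """
    if dialect == "long":
        df = _read_csv(path)
        missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CtDataError(f"long dialect requires columns {LONG_COLUMNS}; missing {missing_cols}")
        dup = df.duplicated(subset=["gene", "sample"], keep=False)
        if dup.any():
            g, s = df.loc[dup, ["gene", "sample"]].iloc[0]
            raise CtDataError(f"duplicate (gene, sample) pair: ({g!r}, {s!r})")
        genes = list(dict.fromkeys(df["gene"]))
        anns = {}
        for _, row in df.drop_duplicates(subset="sample").iterrows():
            anns[row["sample"]] = SampleAnnotation(
                sample_id=row["sample"],
                group=row["group"],
                treatment=row["treatment"],
                biological_replicate=int(row["bio_rep"]),
                technical_replicate=int(row["tech_rep"]),
            )
        sample_ids = list(anns)
        values = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"), columns=sample_ids)
        for _, row in df.iterrows():
            values.at[row["gene"], row["sample"]] = _parse_ct_cell(row["ct"])
        return CtMatrix(values, [anns[i] for i in sample_ids])

    if dialect == "wide":
        if annotations is None:
            raise CtDataError("wide dialect requires an annotation table")
        df = _read_csv(path)
        gene_col = df.columns[0]
        if df[gene_col].duplicated().any():
            g = df[gene_col][df[gene_col].duplicated()].iloc[0]
            raise CtDataError(f"duplicate gene row: {g!r}")
        ann_df = annotations if isinstance(annotations, pd.DataFrame) else _read_csv(annotations)
        need = ["sample", "group", "treatment", "bio_rep", "tech_rep"]
        missing_cols = [c for c in need if c not in ann_df.columns]
        if missing_cols:
            raise CtDataError(f"annotation table missing columns {missing_cols}")
        ann_map = {
            row["sample"]: SampleAnnotation(
                sample_id=row["sample"],
                group=row["group"],
                treatment=row["treatment"],
                biological_replicate=int(row["bio_rep"]),
                technical_replicate=int(row["tech_rep"]),
            )
            for _, row in ann_df.iterrows()
        }
        sample_ids = [c for c in df.columns if c != gene_col]
        unannotated = [c for c in sample_ids if c not in ann_map]
        if unannotated:
            raise CtDataError(f"sample columns without annotation: {unannotated}")
        values = df.set_index(gene_col)[sample_ids].map(_parse_ct_cell)
        values.index.name = "gene"
        return CtMatrix(values, [ann_map[i] for i in sample_ids])

    raise CtDataError(f"unknown dialect {dialect!r} (expected 'wide' or 'long')")


def _metadata_header(metadata: Mapping[str, object] | None) -> str:
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_ct_table(
    m: CtMatrix,
    path,
    dialect: str = "long",
    annotations_path=None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a CtMatrix to CSV, with ``#``-prefixed metadata comment lines.

    The wide dialect writes the annotation sidecar to ``annotations_path``
    when given. Round-trips bit-identically through :func:`read_ct_table`
    (values via repr-exact float formatting).
    """
    header = _metadata_header(metadata)
    if dialect == "long":
        rows = []
        for gene in m.genes:
            for s in m.samples:
                ct = m.values.at[gene, s.sample_id]
                rows.append(
                    {
                        "gene": gene,
                        "sample": s.sample_id,
                        "group": s.group,
                        "treatment": s.treatment,
                        "bio_rep": s.biological_replicate,
                        "tech_rep": s.technical_replicate,
                        "ct": "" if math.isnan(ct) else repr(float(ct)),
                    }
                )
        buf = io.StringIO()
        pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(buf, index=False)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + buf.getvalue())
    elif dialect == "wide":
        out = m.values.copy().astype(object)
        for c in out.columns:
            out[c] = [("" if math.isnan(v) else repr(float(v))) for v in m.values[c]]
        buf = io.StringIO()
        out.to_csv(buf, index_label="gene")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + buf.getvalue())
        if annotations_path is not None:
            ann = m.annotation_frame().rename(
                columns={"biological_replicate": "bio_rep", "technical_replicate": "tech_rep"}
            )
            ann.to_csv(annotations_path, index_label="sample")
    else:
        raise CtDataError(f"unknown dialect {dialect!r}")


def read_efficiency_table(path) -> list[EfficiencyRecord]:
    """Read per-gene efficiencies from CSV (columns: gene, slope, efficiency).

    One of slope/efficiency is required per row; efficiency is derived from
    the slope when absent.
    """
    df = _read_csv(path)
    if "gene" not in df.columns:
        raise CtDataError("efficiency table requires a 'gene' column")
    records = []
    for _, row in df.iterrows():
        slope = row.get("slope")
        eff = row.get("efficiency")
        slope = float(slope) if slope not in (None, "") and not pd.isna(slope) else None
        eff = float(eff) if eff not in (None, "") and not pd.isna(eff) else None
        if eff is None and slope is None:
            raise CtDataError(f"gene {row['gene']!r}: one of slope/efficiency required")
        if eff is None:
            eff = efficiency_from_slope(slope)
        records.append(EfficiencyRecord(gene=row["gene"], efficiency=eff, slope=slope))
    return records


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def collapse_technical_replicates(m: CtMatrix) -> CtMatrix:
    """Average technical replicates into one column per biological sample.

    Each collapsed cell is the arithmetic mean of the non-missing replicate
    Cts (the standard treatment of within-run triplicates); a cell whose
    replicates are all missing stays missing.  Collapsed samples carry
    ``technical_replicate = 0`` and ids ``{group}:{treatment}:b{bio_rep}``.
    """
    keys: list[tuple[str, str, int]] = []
    members: dict[tuple[str, str, int], list[str]] = {}
    for s in m.samples:
        key = (s.group, s.treatment, s.biological_replicate)
        if key not in members:
            members[key] = []
            keys.append(key)
        members[key].append(s.sample_id)

    cols = {}
    anns = []
    for group, treatment, bio in keys:
        new_id = f"{group}:{treatment}:b{bio}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN rows
            cols[new_id] = m.values[members[(group, treatment, bio)]].mean(axis=1)
        anns.append(
            SampleAnnotation(
                sample_id=new_id,
                group=group,
                treatment=treatment,
                biological_replicate=bio,
                technical_replicate=0,
            )
        )
    values = pd.DataFrame(cols, index=m.values.index)
    return CtMatrix(values, anns)


def ct_to_quantity(
    m: CtMatrix,
    efficiencies: Iterable[EfficiencyRecord] | Mapping[str, float] | None = None,
    calibrator: str = "per_gene_min_ct",
    default_efficiency: float = 1.0,
) -> QuantityMatrix:
    """Transform Ct values into efficiency-corrected relative quantities.

    ``quantity(g, s) = (1 + E_g)^(Ct_min(g) - Ct(g, s))`` with the per-gene
    minimum Ct (the most-expressed sample) as calibrator, so the per-gene
    maximum quantity is 1.  Genes without a supplied efficiency use
    ``default_efficiency`` (E = 1, classic 2^-ΔCt).  Missing Cts give missing
    quantities.
    """
    if calibrator != "per_gene_min_ct":
        raise CtDataError(f"unknown calibrator convention {calibrator!r}")
    if efficiencies is None:
        eff_map: dict[str, float] = {}
    elif isinstance(efficiencies, Mapping):
        eff_map = dict(efficiencies)
    else:
        eff_map = {r.gene: r.efficiency for r in efficiencies}

    values = {}
    for gene in m.genes:
        e = float(eff_map.get(gene, default_efficiency))
        if e < 0:
            raise CtDataError(f"gene {gene!r}: efficiency must be >= 0, got {e}")
        row = m.values.loc[gene]
        ct_min = row.min(skipna=True)
        values[gene] = (1.0 + e) ** (ct_min - row)
    q = pd.DataFrame(values).T
    q.index.name = "gene"
    q = q[m.sample_ids]
    return QuantityMatrix(
        q,
        m.samples,
        metadata={
            "calibrator": calibrator,
            "default_efficiency": default_efficiency,
            "efficiencies": {g: float(eff_map.get(g, default_efficiency)) for g in m.genes},
        },
    )


def normalization_factor(q: QuantityMatrix, genes: Sequence[str]) -> pd.Series:
    """Per-sample normalization factor: geometric mean of the selected genes'
    relative quantities (equivalently ``exp(mean(log q))``)."""
    genes = list(genes)
    if not genes:
        raise CtDataError("normalization_factor requires at least one gene")
    unknown = [g for g in genes if g not in set(q.genes)]
    if unknown:
        raise CtDataError(f"genes not in quantity matrix: {unknown}")
    sub = q.values.loc[genes]
    arr = sub.to_numpy(dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise CtDataError("normalization factor requires complete, positive quantities")
    nf = np.exp(np.mean(np.log(arr), axis=0))
    return pd.Series(nf, index=sub.columns, name="normalization_factor")
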