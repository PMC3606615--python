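"""Reading and writing the tab-delimited family genotype table.

One row per sampled individual with the columns

    stratum_id  psu_id  family_id  member_id  role  genotype  weight

where ``role`` is father/mother/child and ``genotype`` one of AA/Aa/aa
(case-insensitive; "aA" normalizes to "Aa").  Exactly three rows, one per
role, must be present for every (stratum, psu, family) key.  Pedigree
formats are not used because stratum/PSU/weight have no slot in them; a
converter from the classic 6-column pedigree layout plus a design sidecar
is provided as a convenience.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .families import FamilyData, SurveyDesign
from .genotypes import GENOTYPE_LABELS, MendelianError, classify_trio

COLUMNS = (
    "stratum_id",
    "psu_id",
    "family_id",
    "member_id",
    "role",
    "genotype",
    "weight",
)
ROLES = ("father", "mother", "child")

FAMILY_WEIGHT_RULES = ("mean", "first", "provided")


class FamilyTableError(ValueError):
    """Malformed or inconsistent family table."""


def _normalize_genotype(label: str, line: int) -> int:
    s = str(label).strip()
    if len(s) != 2 or any(ch not in "Aa" for ch in s):
        raise FamilyTableError(f"line {line}: unrecognized genotype {label!r}")
    return sum(ch == "a" for ch in s)  # copies of allele a = genotype code


def read_family_table(
    path: str | Path,
    family_weight_rule: str = "mean",
    drop_inconsistent: bool = False,
) -> tuple[FamilyData, SurveyDesign, int]:
    """Parse a family table into :class:`FamilyData` and its design.

    ``family_weight_rule`` sets how the family-level weight is built from
    member weights: ``mean`` (default, averaging as in household-survey
    practice) or ``first`` (the father's weight).  Mendelian-inconsistent
    families raise :class:`MendelianError` naming the family unless
    ``drop_inconsistent`` is set, in which case they are removed and their
    count returned as the third element.
    """
    if family_weight_rule not in ("mean", "first"):
        raise ValueError("family_weight_rule must be 'mean' or 'first'")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise FamilyTableError(f"missing column(s): {sorted(missing)}")
    df = df.reset_index().rename(columns={"index": "_line"})
    df["_line"] += 2  # header is line 1

    try:
        df["weight"] = df["weight"].astype(float)
    except ValueError as exc:
        raise FamilyTableError(f"non-numeric weight: {exc}") from exc
    bad_w = df[df["weight"] <= 0]
    if len(bad_w):
        raise FamilyTableError(
            f"line {int(bad_w['_line'].iloc[0])}: non-positive weight"
        )
    df["genotype_code"] = [
        _normalize_genotype(g, line)
        for g, line in zip(df["genotype"], df["_line"])
    ]

    rows = {"stratum": [], "psu": [], "family": [], "genotypes": [],
            "member_w": [], "lines": []}
    for (s, p, f), grp in df.groupby(
        ["stratum_id", "psu_id", "family_id"], sort=True
    ):
        roles = dict(zip(grp["role"].str.lower(), grp.index))
        line0 = int(grp["_line"].iloc[0])
        if len(grp) != 3 or sorted(roles) != sorted(ROLES):
            raise FamilyTableError(
                f"family {f!r} (near line {line0}): needs exactly one "
                f"father, mother and child; got roles {sorted(grp['role'])}"
            )
        g = [int(grp.loc[roles[r], "genotype_code"]) for r in ROLES]
        w = [float(grp.loc[roles[r], "weight"]) for r in ROLES]
        rows["stratum"].append(s)
        rows["psu"].append(p)
        rows["family"].append(f)
        rows["genotypes"].append(g)
        rows["member_w"].append(w)
        rows["lines"].append(line0)

    keep, n_dropped = [], 0
    for i, (g, f, line) in enumerate(
        zip(rows["genotypes"], rows["family"], rows["lines"])
    ):
        try:
            classify_trio(*g)
            keep.append(i)
        except MendelianError as exc:
            if not drop_inconsistent:
                raise MendelianError(
                    f"family {f!r} (near line {line}): {exc}"
                ) from exc
            n_dropped += 1
    if not keep:
        raise FamilyTableError("no valid families in table")

    def codes(values):
        _, inv = np.unique(np.asarray(values, dtype=object)[keep], return_inverse=True)
        return inv

    member_w = np.asarray(rows["member_w"], dtype=float)[keep]
    if family_weight_rule == "mean":
        fam_w = member_w.mean(axis=1)
    else:
        fam_w = member_w[:, 0]
    data = FamilyData(
        stratum=codes(rows["stratum"]),
        psu=codes(rows["psu"]),
        family_id=np.arange(len(keep)),
        genotypes=np.asarray(rows["genotypes"], dtype=np.int8)[keep],
        family_weight=fam_w,
        member_weights=member_w,
    )
    return data, SurveyDesign.from_family_data(data), n_dropped


def write_family_table(data: FamilyData, path: str | Path) -> None:
    """Write a family table with canonical column and row order.

    Rows sorted by (stratum, psu, family, role); byte-identical output for
    identical input, so ``read . write`` round-trips the domain model.
    """
    if data.n_families == 0:
        raise ValueError("no families to write")
    recs = []
    for i in np.lexsort((data.family_id, data.psu, data.stratum)):
        for k, role in enumerate(ROLES):
            recs.append(
                {
                    "stratum_id": int(data.stratum[i]),
                    "psu_id": int(data.psu[i]),
                    "family_id": int(data.family_id[i]),
                    "member_id": f"{int(data.family_id[i])}.{k + 1}",
                    "role": role,
                    "genotype": GENOTYPE_LABELS[int(data.genotypes[i, k])],
                    "weight": repr(float(data.member_weights[i, k])),
                }
            )
    pd.DataFrame(recs, columns=list(COLUMNS)).to_csv(path, sep="\t", index=False)


def read_pedigree_with_design(
    pedigree_path: str | Path, design_path: str | Path
) -> tuple[FamilyData, SurveyDesign, int]:
    """Convenience converter: 6-column pedigree + tab-delimited design sidecar.

    Pedigree columns: family, individual, father, mother, sex, genotype
    (0 for founder parent references).  The sidecar maps ``family_id`` to
    ``stratum_id``, ``psu_id`` and per-role weights (columns
    ``father_weight``, ``mother_weight``, ``child_weight``).
    """
    ped = pd.read_csv(
        pedigree_path,
        sep="\t",
        names=["family", "individual", "father", "mother", "sex", "genotype"],
        dtype=str,
        header=None,
    )
    side = pd.read_csv(design_path, sep="\t", dtype=str)
    rows = []
    for fam, grp in ped.groupby("family", sort=True):
        child = grp[(grp["father"] != "0") & (grp["mother"] != "0")]
        if len(child) != 1:
            raise FamilyTableError(f"family {fam!r}: expected exactly one child")
        child = child.iloc[0]
        meta = side[side["family_id"] == fam]
        if len(meta) != 1:
            raise FamilyTableError(f"family {fam!r}: missing design sidecar row")
        meta = meta.iloc[0]
        by_id = grp.set_index("individual")
        for role, indiv, wcol in (
            ("father", child["father"], "father_weight"),
            ("mother", child["mother"], "mother_weight"),
            ("child", child["individual"], "child_weight"),
        ):
            rows.append(
                {
                    "stratum_id": meta["stratum_id"],
                    "psu_id": meta["psu_id"],
                    "family_id": fam,
                    "member_id": indiv,
                    "role": role,
                    "genotype": by_id.loc[indiv, "genotype"],
                    "weight": meta[wcol],
                }
            )
    import io as _io

    buf = _io.StringIO()
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_family_table(buf)
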