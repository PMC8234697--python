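"""Packaged reference cohorts.

`neovascular_eyes_table` is the published per-patient table of the eight
eyes with subclinical non-exudative macular neovascularization (gender,
age, BCVA, five imaging flags, CMT, CT).  It is the only per-eye clinical
data the study discloses and serves as a reference fixture for the
cohort statistics.

`synthetic_nonneovascular_arm` is a synthetic stand-in for the 89
non-neovascular eyes, whose per-eye data are not deposited: it
reproduces the reported group marginals exactly (flag counts 59/65/37/
50/19 of 89) with arbitrary but deterministic quantitative covariates.
Marginal counts are all that Fisher-exact flag comparisons depend on.
"""

from __future__ import annotations

from .image_io import CohortTable, EyeRecord

__all__ = ["neovascular_eyes_table", "synthetic_nonneovascular_arm", "fixtures_table1"]

# (sex, age, bcva_logmar, small, large, ped, atrophy, rpd, cmt, ct)
_NEOVASCULAR_ROWS = (
    ("F", 72, 0.1, 1, 1, 1, 0, 1, 252, 257),
    ("F", 78, 0.0, 0, 0, 1, 0, 0, 211, 139),
    ("M", 80, 0.2, 0, 0, 1, 0, 0, 338, 136),
    ("M", 82, 0.1, 0, 0, 0, 0, 0, 249, 289),
    ("F", 91, 0.3, 1, 1, 1, 0, 1, 264, 243),
    ("F", 72, 0.1, 1, 1, 1, 0, 1, 244, 382),
    ("F", 89, 0.2, 0, 0, 1, 0, 1, 239, 268),
    ("F", 88, 0.0, 0, 1, 1, 0, 0, 204, 102),
)


def neovascular_eyes_table() -> CohortTable:
    """The eight neovascular study eyes as a :class:`CohortTable`."""
    records = []
    for i, (sex, age, bcva, small, large, ped, atrophy, rpd, cmt, ct) in enumerate(
        _NEOVASCULAR_ROWS, start=1
    ):
        records.append(
            EyeRecord(
                eye_id=f"neo-{i}",
                group="neovascular",
                sex=sex,
                age_years=float(age),
                bcva_logmar=float(bcva),
                cmt_um=float(cmt),
                ct_um=float(ct),
                small_drusen=bool(small),
                large_drusen=bool(large),
                drusenoid_ped=bool(ped),
                rpd=bool(rpd),
                atrophy=bool(atrophy),
            )
        )
    return CohortTable(records)


#: Alias kept for pipeline symmetry: the fixture behind the run-level API.
fixtures_table1 = neovascular_eyes_table

# Reported marginal flag counts in the 89 non-neovascular eyes.
_NON_NEO_FLAG_COUNTS = {
    "small_drusen": 59,
    "large_drusen": 65,
    "drusenoid_ped": 37,
    "rpd": 50,
    "atrophy": 19,
}
_NON_NEO_N = 89


def synthetic_nonneovascular_arm() -> CohortTable:
    """Synthetic 89-eye non-neovascular arm with the reported flag marginals.

    Each flag is set on the first ``count`` eyes, so the joint flag
    distribution is arbitrary while every marginal count is exact.
    Quantitative covariates are constant placeholders (group means) and
    must not be used for quantitative group comparisons.
    """
    records = []
    for i in range(_NON_NEO_N):
        flags = {name: i < count for name, count in _NON_NEO_FLAG_COUNTS.items()}
        records.append(
            EyeRecord(
                eye_id=f"nonneo-{i + 1:02d}",
                group="non_neovascular",
                age_years=79.0,
                bcva_logmar=0.18,
                cmt_um=231.95,
                ct_um=209.09,
                **flags,
            )
        )
    return CohortTable(records)
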