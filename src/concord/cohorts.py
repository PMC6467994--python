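"""Build cohorts and agreement lists directly from tabulated counts.

Published cohort tables report *counts* — how many eyes carried each
lesion-type combination, how many were acute, how many matched areas
were classified equal — not per-eye data.  These builders expand such
counts into explicit :class:`~concord.io_annotations.EyeRecord` and
:class:`~concord.agreement.AgreementResult` lists so that
:func:`~concord.agreement.cohort_summary` can recompute every derived
percentage from first principles.

The lesion-combination model follows the clinical structure of the
disease: the dark halo (type B) only occurs around a hyper-reflective
patch (type A), and hypo-reflective spots (type C) occur in every eye,
so the observed combinations are "all three", "A and C only" and
"C only".
"""

from __future__ import annotations

from .agreement import AgreementResult
from .errors import ConfigError
from .io_annotations import EyeRecord

__all__ = ["cohort_from_counts", "agreements_from_counts"]


def cohort_from_counts(
    n_all_three: int,
    n_a_c_only: int,
    n_c_only: int,
    n_acute: int,
    n_type_b_acute: int | None = None,
) -> list[EyeRecord]:
    """Expand combination counts into explicit per-eye records.

    Parameters
    ----------
    n_all_three, n_a_c_only, n_c_only
        Eyes with types A+B+C, with A+C but no halo, and with C only.
        Their sum is the cohort size.
    n_acute
        Eyes with acute disease (symptom duration <= 6 months).
    n_type_b_acute
        How many of the halo-positive eyes are acute.  Defaults to as
        many as fit; must not exceed either the halo count or the acute
        count, and the remaining halo eyes must fit among the chronic.
    """
    n = n_all_three + n_a_c_only + n_c_only
    n_chronic = n - n_acute
    if n_acute < 0 or n_chronic < 0:
        raise ConfigError("acute count exceeds cohort size")
    if n_type_b_acute is None:
        n_type_b_acute = min(n_all_three, n_acute)
    n_type_b_chronic = n_all_three - n_type_b_acute
    if not 0 <= n_type_b_acute <= min(n_all_three, n_acute):
        raise ConfigError("n_type_b_acute out of range")
    if n_type_b_chronic > n_chronic:
        raise ConfigError("halo-positive chronic eyes exceed the chronic count")

    # flags per eye: halo eyes first, then A+C, then C-only
    flags = (
        [(True, True, True)] * n_all_three
        + [(True, False, True)] * n_a_c_only
        + [(False, False, True)] * n_c_only
    )
    # duration: acute slots go to the first n_type_b_acute halo eyes, the
    # rest of the acute quota to halo-negative eyes
    duration = ["chronic"] * n
    acute_left = n_acute
    for i in range(n_type_b_acute):
        duration[i] = "acute"
        acute_left -= 1
    for i in range(n_all_three, n):
        if acute_left == 0:
            break
        duration[i] = "acute"
        acute_left -= 1
    # any remaining acute quota goes to halo eyes beyond n_type_b_acute —
    # only possible if the caller asked for fewer acute halo eyes than fit
    i = n_type_b_acute
    while acute_left > 0:
        if duration[i] == "chronic" and i < n_all_three + n_a_c_only + n_c_only:
            duration[i] = "acute"
            acute_left -= 1
        i += 1

    return [
        EyeRecord(
            eye_id=f"eye-{i:03d}",
            duration_class=duration[i],
            has_type_a=a,
            has_type_b=b,
            has_type_c=c,
        )
        for i, (a, b, c) in enumerate(flags)
    ]


def agreements_from_counts(
    n_equal: int,
    n_larger: int,
    n_smaller: int = 0,
    comparison: str = "octa_vs_icga",
) -> list[AgreementResult]:
    """Expand area-relation counts into explicit agreement results.

    The Jaccard values and areas are placeholders consistent with each
    relation (equal within 10%, larger/smaller outside it); only the
    relation tallies matter to the counts a summary reports.
    """
    results = []
    specs = (
        ("equal", n_equal, 10.0, 10.0),
        ("larger", n_larger, 12.0, 10.0),
        ("smaller", n_smaller, 8.0, 10.0),
    )
    i = 0
    for relation, count, a_octa, a_icga in specs:
        for _ in range(count):
            results.append(
                AgreementResult(
                    eye_id=f"eye-{i:03d}",
                    comparison=comparison,
                    jaccard=0.84,
                    area_first=a_octa,
                    area_second=a_icga,
                    relation=relation,
                )
            )
            i += 1
    return results
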