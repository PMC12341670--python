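"""Shared fixtures: synthetic exams, site masters, and the audit cohort.

Everything is generated programmatically at test time; no binary fixtures
are stored in the repository.
"""

from __future__ import annotations

import itertools
import os

import pandas as pd
import pytest

from protoqc import audit as au
from protoqc import fixtures as fx
from protoqc.checker import check_exam
from protoqc.dicom_io import (
    ACQUISITION_NUMBER,
    InstanceRecord,
    SERIES_DESCRIPTION,
    SERIES_NUMBER,
    SLICE_LOCATION,
    TEMPORAL_POSITION,
    read_exam,
)
from protoqc.master import generate_master


def make_instance(path="mem", sn=None, an=None, sl=None, tpi=None, desc=None, extra=None):
    """Build an in-memory InstanceRecord for unit tests (``extra`` maps
    TagRef -> value)."""
    tags = {}
    if sn is not None:
        tags[SERIES_NUMBER] = sn
    if an is not None:
        tags[ACQUISITION_NUMBER] = an
    if sl is not None:
        tags[SLICE_LOCATION] = sl
    if tpi is not None:
        tags[TEMPORAL_POSITION] = tpi
    if desc is not None:
        tags[SERIES_DESCRIPTION] = desc
    tags.update(extra or {})
    return InstanceRecord(source_path=path, tags=tags)


def brute_force_assignment(agree: dict[tuple[int, int], int], n_specs: int, n_series: int) -> int:
    """Exhaustive best total parameter agreement over all injective
    spec -> series mappings restricted to candidate pairs."""
    best = 0
    series_opts = list(range(n_series)) + [None]
    for choice in itertools.product(series_opts, repeat=n_specs):
        used = [r for r in choice if r is not None]
        if len(used) != len(set(used)):
            continue
        total = 0
        ok = True
        for si, ri in enumerate(choice):
            if ri is None:
                continue
            if (si, ri) not in agree:
                ok = False
                break
            total += agree[(si, ri)]
        if ok:
            best = max(best, total)
    return best


@pytest.fixture(scope="session")
def templates():
    return fx.site_templates()


@pytest.fixture(scope="session")
def siemens_exam(tmp_path_factory, templates):
    """A pristine Siemens examination directory (site 1 protocol)."""
    root = tmp_path_factory.mktemp("siemens")
    return fx.make_exam(templates["site01"], "exemplar01", str(root), seed=11)


@pytest.fixture(scope="session")
def tier2_attrs():
    return fx.tier2_attributes()


@pytest.fixture(scope="session")
def tier1_attrs():
    return fx.tier1_attributes()


@pytest.fixture(scope="session")
def cohort_audit(tmp_path_factory):
    """The full synthetic 174-exam cohort, checked at both tiers.

    Returns a namespace with the cohort spec, per-exam results, matrices,
    summaries, site map and the count of unhandled checker failures.
    """
    spec = fx.table3_cohort_spec(seed=123)
    root = tmp_path_factory.mktemp("cohort")
    cohort_dir = str(root / "exams")
    fx.make_cohort(spec, cohort_dir)

    t1_attrs = fx.tier1_attributes()
    t2_attrs = fx.tier2_attributes()
    exemplar_dir = str(root / "exemplars")
    site_masters = {}
    for site, template in fx.site_templates().items():
        d = fx.make_exam(template, f"{site}_exemplar", exemplar_dir, seed=77)
        site_masters[site] = generate_master(read_exam(d, t2_attrs), t2_attrs)
    tier1_master = fx.myrads_tier1_master()

    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.csv"))
    site_of = dict(zip(manifest.exam_id.astype(str), manifest.site.astype(str)))

    results_t1, results_t2, unhandled = [], [], 0
    for exam_id in sorted(site_of):
        exam_dir = os.path.join(cohort_dir, exam_id)
        try:
            results_t1.append(check_exam(read_exam(exam_dir, t1_attrs), tier1_master))
            results_t2.append(
                check_exam(read_exam(exam_dir, t2_attrs), site_masters[site_of[exam_id]])
            )
        except Exception:
            unhandled += 1

    matrix1 = au.build_matrix(results_t1, au.TIER1, site_of)
    matrix2 = au.build_matrix(results_t2, au.TIER2, site_of)

    class Cohort:
        pass

    cohort = Cohort()
    cohort.spec = spec
    cohort.dir = cohort_dir
    cohort.site_of = site_of
    cohort.site_masters = site_masters
    cohort.tier1_master = tier1_master
    cohort.results_t1 = results_t1
    cohort.results_t2 = results_t2
    cohort.matrix1 = matrix1
    cohort.matrix2 = matrix2
    cohort.summary1 = au.summarize(matrix1)
    cohort.summary2 = au.summarize(matrix2)
    cohort.unhandled = unhandled
    return cohort
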