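"""Clinical table I/O, design encoding, volumes, MIP, splitting."""

import numpy as np
import pandas as pd
import pytest

from survfusion import make_records
from survfusion.data import (
    PETVolume,
    coronal_mip,
    decode_design_row,
    design_column_names,
    encode_design,
    load_volume,
    normalize_volume,
    read_clinical_table,
    save_volume,
    split_cohort,
    stratified_kfold,
    write_clinical_table,
)
from survfusion.data import ClinicalFeatures


def make_features(**overrides):
    base = dict(
        subject_id="p1",
        age=65.0,
        sex="female",
        histology="NOS",
        t_stage="T1",
        n_stage="N0",
        m_stage="M0",
        overall_stage="I",
        smoking_history="ever",
        smoking_amount=20.0,
    )
    base.update(overrides)
    return ClinicalFeatures(**base)


def write_csv(path, rows):
    pd.DataFrame(rows).to_csv(path, index=False)


def csv_row(**overrides):
    row = dict(
        subject_id="p1", age=65, sex="male", histology="adenocarcinoma",
        t_stage="T2", n_stage="N1", m_stage="M0", overall_stage="II",
        smoking_history="ever", smoking_amount=30, os_days=400, event=1,
    )
    row.update(overrides)
    return row


class TestReadClinicalTable:
    def test_well_formed_rows_load(self, tmp_path):
        path = tmp_path / "c.csv"
        write_csv(path, [csv_row(subject_id=f"p{i}") for i in range(3)])
        table = read_clinical_table(path)
        assert len(table.features) == 3 and not table.rejected

    def test_bad_stage_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "c.csv"
        write_csv(path, [csv_row(), csv_row(subject_id="p2", overall_stage="V")])
        table = read_clinical_table(path)
        assert len(table.features) == 1
        assert table.rejected[0][0] == 2
        assert "overall_stage" in table.rejected[0][1]

    def test_missing_value_excludes_only_that_row(self, tmp_path):
        path = tmp_path / "c.csv"
        write_csv(
            path,
            [csv_row(), csv_row(subject_id="p2", smoking_amount=None), csv_row(subject_id="p3")],
        )
        table = read_clinical_table(path)
        assert [f.subject_id for f in table.features] == ["p1", "p3"]
        assert len(table.rejected) == 1

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "c.csv"
        row = csv_row()
        row.pop("age")
        write_csv(path, [row])
        with pytest.raises(ValueError, match="age"):
            read_clinical_table(path)

    def test_round_trip(self, tmp_path):
        feats = [make_features(subject_id=f"p{i}") for i in range(4)]
        recs = make_records([10, 20, 30, 40], [1, 0, 1, 0], [f.subject_id for f in feats])
        path = tmp_path / "c.csv"
        write_clinical_table(path, feats, recs)
        table = read_clinical_table(path)
        assert table.features == feats
        assert [r.time for r in table.records] == [10, 20, 30, 40]


class TestEncodeDesign:
    def test_column_count_is_seventeen(self):
        assert len(design_column_names()) == 17

    def test_reference_subject_has_zero_one_hot_block(self):
        d = encode_design([make_features()])
        names = d.column_names
        onehot = [j for j, c in enumerate(names) if "=" in c]
        assert np.all(d.matrix[0, onehot] == 0)
        assert d.matrix[0, names.index("age")] == 65.0
        assert d.matrix[0, names.index("smoking_amount")] == 20.0

    def test_two_nonzero_dummies_for_male_t2(self):
        d = encode_design([make_features(sex="male", t_stage="T2")])
        onehot = [j for j, c in enumerate(d.column_names) if "=" in c]
        hot = [d.column_names[j] for j in onehot if d.matrix[0, j] == 1.0]
        assert sorted(hot) == ["sex=male", "t_stage=T2"]

    def test_decode_round_trip(self, rng):
        levels = dict(
            sex=["female", "male"],
            histology=["NOS", "adenocarcinoma", "large_cell", "squamous"],
            t_stage=["T1", "T2", "T3", "T4"],
            n_stage=["N0", "N1", "N2", "N3"],
            m_stage=["M0", "M1"],
            overall_stage=["I", "II", "III", "IV"],
        )
        feats = []
        for i in range(20):
            choice = {k: str(rng.choice(v)) for k, v in levels.items()}
            feats.append(make_features(subject_id=f"p{i}", **choice))
        d = encode_design(feats)
        for i, f in enumerate(feats):
            decoded = decode_design_row(d, i)
            for k in levels:
                assert decoded[k] == getattr(f, k)

    def test_unseen_level_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_features(histology="carcinoid")

    def test_never_smoker_with_pack_years_rejected(self):
        with pytest.raises(ValueError):
            make_features(smoking_history="never", smoking_amount=10.0)


class TestVolumes:
    def test_nifti_round_trip(self, tmp_path, rng):
        data = rng.uniform(0, 2, (8, 9, 10)).astype(np.float32)
        vol = PETVolume(data=data, spacing=(4.0, 4.0, 4.0))
        path = tmp_path / "v.nii.gz"
        save_volume(vol, path)
        back = load_volume(path)
        np.testing.assert_allclose(back.data, data, rtol=1e-6)
        assert back.spacing == (4.0, 4.0, 4.0)
        assert back.axes == ("LR", "AP", "IS")

    def test_negative_intensities_clipped(self, tmp_path, rng):
        import nibabel as nib

        data = rng.normal(0, 1, (5, 5, 5)).astype(np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "v.nii"))
        vol = load_volume(tmp_path / "v.nii")
        assert vol.data.min() >= 0

    def test_non_3d_rejected(self, tmp_path, rng):
        import nibabel as nib

        data = rng.uniform(0, 1, (4, 4, 4, 3)).astype(np.float32)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(tmp_path / "v4.nii"))
        with pytest.raises(ValueError, match="3-D"):
            load_volume(tmp_path / "v4.nii")

    def test_normalize_constant_volume_is_all_ones(self):
        vol = PETVolume(np.full((4, 4, 4), 3.5))
        out = normalize_volume(vol)
        np.testing.assert_allclose(out.data, 1.0)

    def test_normalize_clips_above_ceiling(self):
        data = np.full((4, 4, 4), 0.5)
        data[0, 0, 0] = 9.0
        out = normalize_volume(PETVolume(data), clip_max=1.0)
        assert out.data[0, 0, 0] == 1.0
        assert out.data[1, 1, 1] == pytest.approx(0.5)

    def test_normalize_deterministic(self, rng):
        data = rng.uniform(0, 5, (6, 6, 6))
        a = normalize_volume(PETVolume(data.copy()))
        b = normalize_volume(PETVolume(data.copy()))
        assert np.array_equal(a.data, b.data)

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(ValueError):
            normalize_volume(PETVolume(np.zeros((3, 3, 3))))


class TestCoronalMIP:
    def test_single_voxel_projects_to_lr_is_position(self):
        data = np.zeros((6, 7, 8))
        data[2, 3, 5] = 9.0
        mip = coronal_mip(PETVolume(data))
        assert mip.shape == (6, 8)
        assert mip[2, 5] == 9.0 and mip.sum() == 9.0

    def test_constant_volume_projects_to_constant(self):
        mip = coronal_mip(PETVolume(np.full((4, 5, 6), 2.5)))
        np.testing.assert_allclose(mip, 2.5)

    def test_matches_loop_oracle(self, rng):
        data = rng.uniform(0, 10, (5, 6, 7))
        mip = coronal_mip(PETVolume(data))
        for i in range(5):
            for k in range(7):
                assert mip[i, k] == max(data[i, j, k] for j in range(6))

    def test_idempotent_on_unit_ap_extent(self, rng):
        data = rng.uniform(0, 1, (5, 1, 7))
        mip = coronal_mip(PETVolume(data))
        np.testing.assert_array_equal(mip, data[:, 0, :])

    def test_missing_ap_axis_rejected(self, rng):
        vol = PETVolume(rng.uniform(0, 1, (4, 4, 4)), axes=("LR", "SI", "IS"))
        with pytest.raises(ValueError, match="anterior"):
            coronal_mip(vol)


class TestSplitting:
    def test_exact_event_divisibility(self):
        recs = make_records(np.arange(1, 101.0), [1] * 30 + [0] * 70)
        for tr, te in stratified_kfold(recs, k=5, seed=0):
            assert np.array([r.event for r in recs])[te].sum() == 6

    def test_folds_disjoint_and_exhaustive(self, rng):
        t, e = rng.uniform(1, 100, 103), rng.integers(0, 2, 103)
        recs = make_records(t, e)
        folds = stratified_kfold(recs, k=5, seed=3)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(103))
        for tr, te in folds:
            assert not set(tr) & set(te)
            assert sorted(set(tr) | set(te)) == list(range(103))

    def test_same_seed_reproduces_folds(self, rng):
        recs = make_records(rng.uniform(1, 10, 60), rng.integers(0, 2, 60))
        a = stratified_kfold(recs, k=4, seed=9)
        b = stratified_kfold(recs, k=4, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tea, teb)

    def test_event_balance_within_two_points(self, rng):
        e = (rng.random(500) < 0.31).astype(int)
        recs = make_records(rng.uniform(1, 100, 500), e)
        rate = e.mean()
        for _, te in stratified_kfold(recs, k=5, seed=1):
            fold_rate = e[te].mean()
            assert abs(fold_rate - rate) < 0.02

    def test_80_20_split_event_allocation(self, rng):
        # cohort-sized split: 2687 subjects, 1857 events -> ~372 test events
        e = np.zeros(2687, int)
        e[:1857] = 1
        e = e[rng.permutation(2687)]
        recs = make_records(rng.uniform(1, 3000, 2687), e)
        tr, te = split_cohort(recs, fraction=0.8, seed=0)
        assert len(te) == 538
        assert abs(e[te].sum() - 372) <= 2

    def test_small_stratum_error_names_it(self):
        recs = make_records([1, 2, 3, 4, 5, 6.0], [1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="event=1"):
            stratified_kfold(recs, k=3, seed=0)

    def test_split_manifest_round_trip(self, tmp_path, rng):
        from survfusion.data import load_split_manifest, save_split_manifest

        recs = make_records(rng.uniform(1, 10, 40), rng.integers(0, 2, 40))
        folds = stratified_kfold(recs, k=4, seed=11)
        path = tmp_path / "splits.json"
        save_split_manifest(path, recs, folds, seed=11, stratify_on="event")
        back = load_split_manifest(path)
        assert back["seed"] == 11 and back["stratify_on"] == "event"
        ids = [r.subject_id for r in recs]
        for fold, (tr, te) in zip(back["folds"], folds):
            assert fold["test"] == [ids[i] for i in te]
            assert fold["train"] == [ids[i] for i in tr]
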