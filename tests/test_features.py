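"""Annotation-table curation: loading, exclusions, imputation, encoding."""

import numpy as np
import pandas as pd
import pytest

from asepred import (FeatureMatrix, FeatureSpec, apply_exclusions,
                     canonical_exclusions, canonical_feature_names,
                     canonical_specs, impute_and_encode, load_annotations)
from asepred.features import UNKNOWN_CATEGORY, canonical_feature_kinds


def toy_specs():
    return [FeatureSpec("score", "numeric"),
            FeatureSpec("cons", "categorical"),
            FeatureSpec("flag", "binary")]


def toy_file(tmp_path, rows):
    path = tmp_path / "anno.tsv"
    lines = ["locus_id\tscore\tcons\tflag"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestCanonicalCuration:
    def test_header_has_109_names(self):
        names = canonical_feature_names()
        assert len(names) == 109
        assert len(set(names)) == 109

    def test_exclusion_lists_are_12_16_11(self):
        excl = canonical_exclusions()
        assert len(excl["non_functional"]) == 12
        assert len(excl["high_missingness"]) == 16
        assert len(excl["detectability_correlated"]) == 11

    def test_70_features_retained(self):
        matrix = FeatureMatrix(
            pd.DataFrame(np.zeros((1, 109)), columns=canonical_feature_names(),
                         index=["chr1:1:A:G"]).astype(object),
            canonical_specs())
        curated = apply_exclusions(matrix)
        assert curated.shape[1] == 70
        for name in ("GerpN", "bStatistic", "Dist2Mutation", "cDNApos",
                     "minDistTSE", "cHmmReprPCWk", "cHmmQuies", "pLI_score"):
            assert name in curated.feature_names
        assert "gnomAD_AF" not in curated.feature_names

    def test_kinds_cover_header(self):
        kinds = canonical_feature_kinds()
        assert set(kinds) == set(canonical_feature_names())
        assert set(kinds.values()) <= {"numeric", "categorical", "binary"}


class TestLoad:
    def test_identity_load(self, tmp_path):
        path = toy_file(tmp_path, [("chr1:5:A:G", 1.5, "HIGH", "Y")])
        m = load_annotations(path, toy_specs())
        assert m.shape == (1, 3)
        assert not m.missing_mask.any().any()
        assert m.values.loc["chr1:5:A:G", "score"] == 1.5

    def test_na_cell_marked_missing(self, tmp_path):
        path = toy_file(tmp_path, [("chr1:5:A:G", "NA", "HIGH", "Y")])
        m = load_annotations(path, toy_specs())
        assert bool(m.missing_mask.loc["chr1:5:A:G", "score"])

    def test_unparseable_numeric_marked_missing(self, tmp_path):
        path = toy_file(tmp_path, [("chr1:5:A:G", "abc", "HIGH", "Y")])
        m = load_annotations(path, toy_specs())
        assert bool(m.missing_mask.loc["chr1:5:A:G", "score"])

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text("locus_id\tscore\tmystery\n" "chr1:5:A:G\t1\t2\n")
        with pytest.raises(ValueError, match="mystery"):
            load_annotations(path, [FeatureSpec("score", "numeric")])

    def test_duplicate_row_ids_rejected(self, tmp_path):
        path = toy_file(tmp_path, [("chr1:5:A:G", 1, "A", "Y"),
                                   ("chr1:5:A:G", 2, "B", "N")])
        with pytest.raises(ValueError, match="duplicate"):
            load_annotations(path, toy_specs())

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            {"score": rng.normal(size=20).round(6),
             "cons": rng.choice(["A", "B"], 20),
             "flag": rng.choice(["Y", "N"], 20)},
            index=pd.Index([f"chr1:{i}:A:G" for i in range(20)], name="locus_id"))
        m = FeatureMatrix(values.astype(object), toy_specs())
        out = tmp_path / "m.tsv"
        m.to_tsv(out)
        back = load_annotations(out, toy_specs())
        np.testing.assert_allclose(back.values["score"].astype(float),
                                   values["score"].astype(float))
        assert (back.values["cons"] == values["cons"]).all()


class TestExclusions:
    def test_empty_lists_identity(self, tmp_path):
        m = load_annotations(toy_file(tmp_path, [("chr1:5:A:G", 1, "A", "Y")]),
                             toy_specs())
        out = apply_exclusions(m, {})
        assert out.feature_names == m.feature_names

    def test_set_difference_preserves_order(self):
        names = [f"f{i}" for i in range(10)]
        specs = [FeatureSpec(n, "numeric") for n in names]
        values = pd.DataFrame(np.zeros((3, 10)), columns=names,
                              index=["a", "b", "c"])
        out = apply_exclusions(FeatureMatrix(values, specs),
                               {"non_functional": ["f1", "f4", "f9"]})
        assert out.feature_names == [n for n in names if n not in {"f1", "f4", "f9"}]

    def test_unknown_name_rejected(self):
        specs = [FeatureSpec("a", "numeric")]
        m = FeatureMatrix(pd.DataFrame({"a": [1.0]}, index=["x"]), specs)
        with pytest.raises(ValueError, match="ghost"):
            apply_exclusions(m, {"non_functional": ["ghost"]})

    def test_idempotent_on_own_output(self):
        names = [f"f{i}" for i in range(5)]
        specs = [FeatureSpec(n, "numeric") for n in names]
        m = FeatureMatrix(pd.DataFrame(np.zeros((2, 5)), columns=names,
                                       index=["a", "b"]), specs)
        once = apply_exclusions(m, {"non_functional": ["f0"]})
        twice = apply_exclusions(once, {})
        assert twice.feature_names == once.feature_names


class TestImputeEncode:
    def _matrix(self):
        values = pd.DataFrame({
            "score": [1.0, np.nan, 3.0, np.nan],
            "cons": ["B", "A", None, "B"],
            "flag": ["Y", None, "N", "Y"],
        }, index=[f"r{i}" for i in range(4)]).astype(object)
        return FeatureMatrix(values, toy_specs())

    def test_constant_fill(self):
        specs = [FeatureSpec("score", "numeric", imputation_default=0.0)]
        values = pd.DataFrame({"score": [np.nan, 2.0, np.nan]}, index=list("abc"))
        out = impute_and_encode(FeatureMatrix(values, specs))
        assert out.values["score"].tolist() == [0.0, 2.0, 0.0]

    def test_alphabetical_codes_and_no_missing(self):
        out = impute_and_encode(self._matrix())
        assert not out.values.isna().any().any()
        assert np.isfinite(out.values.to_numpy(dtype=float)).all()
        assert out.encoding["categories"]["cons"] == {"A": 0, "B": 1}
        # missing cons imputed with the modal category B -> code 1
        assert out.values.loc["r2", "cons"] == 1

    def test_encoding_is_pure_function_of_matrix(self):
        a = impute_and_encode(self._matrix())
        b = impute_and_encode(self._matrix())
        assert a.encoding == b.encoding
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_unseen_category_maps_to_unknown_code(self):
        train = impute_and_encode(self._matrix())
        new = pd.DataFrame({"score": [5.0], "cons": ["Z"], "flag": ["Y"]},
                           index=["new"]).astype(object)
        applied = impute_and_encode(FeatureMatrix(new, toy_specs()),
                                    encoding=train.encoding)
        assert applied.values.loc["new", "cons"] == len(train.encoding["categories"]["cons"])
        assert applied.shape[0] == 1

    def test_placeholder_default_is_median(self):
        out = impute_and_encode(self._matrix())
        assert out.encoding["defaults"]["score"] == 2.0
        assert out.values.loc["r1", "score"] == 2.0

    def test_binary_with_three_levels_rejected(self):
        values = pd.DataFrame({"flag": ["Y", "N", "M"]}, index=list("abc")).astype(object)
        with pytest.raises(ValueError, match="binary"):
            impute_and_encode(FeatureMatrix(values, [FeatureSpec("flag", "binary")]))
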