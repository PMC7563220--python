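"""Tissue registry and segmentation-scheme behavior."""

import json

import pytest

from htplan.tissues import (
    DETAILED_LABELS,
    SCHEME_NAMES,
    PropertyTable,
    SegmentationScheme,
    TissueProperties,
    TissueValidationError,
    build_scheme,
    default_property_table,
    default_schemes,
    load_property_table,
)


class TestPropertyTable:
    @pytest.mark.parametrize(
        "tissue, eps_r, sigma, rho",
        [
            ("muscle", 66.0, 0.708, 1090),
            ("urine", 49.9, 1.750, 1024),
            ("gtv", 70.0, 0.750, 1050),
            ("small_intestine_lumen", 80.0, 2.000, 1000),
            # the lumen of the large intestine deliberately carries
            # muscle-identical constants in the shipped table
            ("large_intestine_lumen", 66.0, 0.708, 1090),
            ("water", 80.9, 0.002, 1000),
        ],
    )
    def test_shipped_100mhz_values(self, table, tissue, eps_r, sigma, rho):
        t = table[tissue]
        assert (t.eps_r, t.sigma_eff, t.rho) == (eps_r, sigma, rho)

    def test_shipped_table_has_fourteen_rows(self, table):
        assert len(table) == 14

    def test_aliases_resolve_to_fat(self, table):
        assert table.resolve("sat") == table["fat"]
        assert table.resolve("visceral_fat") == table["fat"]
        with pytest.raises(KeyError):
            table.resolve("kidney")

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(tissue_id="x", eps_r=10, sigma_eff=0.1, rho=0.0), "rho"),
            (dict(tissue_id="x", eps_r=10, sigma_eff=-0.1, rho=1000), "sigma_eff"),
            (dict(tissue_id="x", eps_r=0.5, sigma_eff=0.1, rho=1000), "eps_r"),
            (dict(tissue_id="x", eps_r=float("nan"), sigma_eff=0.1, rho=1000), "finite"),
        ],
    )
    def test_invalid_records_rejected(self, kwargs, match):
        with pytest.raises(TissueValidationError, match=match):
            TissueProperties(**kwargs)

    def test_shell_exempt_from_unit_permittivity_bound(self):
        # synthetic casing material, not a biological tissue
        TissueProperties("applicator_shell", eps_r=2.0, sigma_eff=0.004, rho=1180)

    def test_load_rejects_missing_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps([{"tissue_id": "muscle", "eps_r": 66.0, "rho": 1090}]))
        with pytest.raises(TissueValidationError, match="muscle"):
            load_property_table(path)

    def test_load_roundtrip(self, tmp_path, table):
        path = tmp_path / "table.json"
        path.write_text(
            json.dumps(
                [
                    {"tissue_id": t.tissue_id, "eps_r": t.eps_r,
                     "sigma_eff": t.sigma_eff, "rho": t.rho}
                    for t in table
                ]
            )
        )
        loaded = load_property_table(path)
        assert len(loaded) == len(table)
        assert loaded["urine"] == table["urine"]


class TestSchemes:
    def test_detailed_is_identity(self):
        s = build_scheme("detailed")
        assert all(s.apply(lab) == lab for lab in DETAILED_LABELS)

    @pytest.mark.parametrize(
        "scheme, label, expected",
        [
            ("clinical", "urine", "muscle"),  # empty-bladder convention
            ("clinical", "bladder_wall", "muscle"),
            ("clinical", "small_intestine_lumen", "muscle"),
            ("clinical", "sat", "fat"),
            ("clinical", "visceral_fat", "fat"),
            ("clinical", "bone_marrow", "cortical_bone"),
            ("bladder", "urine", "urine"),
            ("bladder", "bladder_wall", "bladder_wall"),
            ("bladder", "small_intestine_wall", "muscle"),
            ("bone_type", "bone_marrow", "bone_marrow"),
            ("bone_type", "cancellous_bone", "cancellous_bone"),
            ("intestine", "large_intestine_lumen", "large_intestine_lumen"),
            ("intestine", "urine", "muscle"),
            ("bladder_and_intestine", "urine", "urine"),
            ("bladder_and_intestine", "small_intestine_lumen", "small_intestine_lumen"),
            ("combined", "bone_marrow", "bone_marrow"),
            ("combined", "urine", "urine"),
        ],
    )
    def test_reduction_rules(self, scheme, label, expected):
        assert build_scheme(scheme).apply(label) == expected

    @pytest.mark.parametrize("name", SCHEME_NAMES)
    def test_gtv_always_preserved(self, name):
        assert build_scheme(name).apply("gtv") == "gtv"

    @pytest.mark.parametrize("name", SCHEME_NAMES)
    def test_application_is_idempotent(self, name):
        s = build_scheme(name)
        for lab in DETAILED_LABELS:
            once = s.apply(lab)
            assert s.apply(once) == once

    @pytest.mark.parametrize(
        "name, allowed",
        [
            ("clinical", {"fat", "muscle", "cortical_bone", "gtv"}),
            ("bone_type", {"fat", "muscle", "cortical_bone", "gtv",
                           "bone_marrow", "cancellous_bone"}),
            ("bladder", {"fat", "muscle", "cortical_bone", "gtv",
                         "urine", "bladder_wall"}),
            ("intestine", {"fat", "muscle", "cortical_bone", "gtv",
                           "small_intestine_wall", "small_intestine_lumen",
                           "large_intestine_wall", "large_intestine_lumen"}),
        ],
    )
    def test_retained_sets_match_delineation_lists(self, name, allowed):
        assert build_scheme(name).retained <= allowed

    def test_combined_retained_is_union(self):
        union = (
            build_scheme("bone_type").retained
            | build_scheme("bladder").retained
            | build_scheme("intestine").retained
        )
        assert build_scheme("combined").retained == union

    def test_unknown_scheme_rejected(self):
        with pytest.raises(TissueValidationError, match="unknown scheme"):
            build_scheme("ultra")

    def test_unclassified_extra_label_rejected(self):
        with pytest.raises(TissueValidationError, match="kidney"):
            build_scheme("clinical", list(DETAILED_LABELS) + ["kidney"])

    def test_extra_label_with_class_maps(self):
        s = build_scheme(
            "clinical", list(DETAILED_LABELS) + ["kidney"],
            extra_classes={"kidney": "high_water"},
        )
        assert s.apply("kidney") == "muscle"

    def test_partial_mapping_raises_on_apply(self):
        s = SegmentationScheme("clinical", {"muscle": "muscle"})
        with pytest.raises(TissueValidationError, match="urine"):
            s.apply("urine")

    def test_gtv_must_map_to_itself(self):
        with pytest.raises(TissueValidationError):
            SegmentationScheme("clinical", {"gtv": "muscle"})

    def test_shipped_schemes_match_builder(self):
        shipped = default_schemes()
        assert set(shipped) == set(SCHEME_NAMES)
        for name, scheme in shipped.items():
            assert scheme.mapping == build_scheme(name).mapping

    def test_retained_ids_exist_in_property_table(self, table):
        for name in SCHEME_NAMES:
            for retained in build_scheme(name).retained:
                assert retained in table
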