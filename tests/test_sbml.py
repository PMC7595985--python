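"""SBML exchange: validity, byte-stable round trips, paired simulation."""

import numpy as np
import pytest

import cannakin as ck
from cannakin.errors import SBMLReadError, UnsupportedRateLawError
from cannakin.sbml_io import export_sbml, import_sbml, sbml_string
from cannakin.synthetic import toy_chain_model


@pytest.fixture(scope="module")
def exported(default_model, tmp_path_factory):
    path = tmp_path_factory.mktemp("sbml") / "thca.xml"
    export_sbml(default_model, path)
    return path


class TestExport:
    def test_document_passes_schema_consistency(self, exported):
        import libsbml
        doc = libsbml.readSBML(str(exported))
        assert doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) == 0
        doc.checkConsistency()
        errors = [doc.getError(i) for i in range(doc.getNumErrors())]
        assert not [e.getMessage() for e in errors
                    if e.getSeverity() >= libsbml.LIBSBML_SEV_ERROR]

    def test_clamped_species_flagged_as_boundary(self, exported):
        import libsbml
        model = libsbml.readSBML(str(exported)).getModel()
        assert model.getSpecies("ha_ex").getBoundaryCondition()
        assert not model.getSpecies("glc_ex").getBoundaryCondition()
        assert model.getNumReactions() == 25


class TestRoundTrip:
    def test_export_import_export_is_byte_stable(self, default_model, exported,
                                                 tmp_path):
        first = sbml_string(default_model)
        back = import_sbml(exported)
        second = sbml_string(back)
        assert first == second

    def test_reimported_model_validates_and_matches(self, default_model, exported):
        back = import_sbml(exported)
        assert ck.validate_model(back) == []
        assert back.content_hash() == default_model.content_hash()

    def test_paired_simulation_within_1e8_mM(self, default_model, exported):
        back = import_sbml(exported)
        a = ck.simulate(default_model, t_end=10.0, dt_out=0.5)
        b = ck.simulate(back, t_end=10.0, dt_out=0.5)
        assert a.species_ids == b.species_ids
        assert np.abs(a.conc - b.conc).max() < 1e-8

    def test_toy_model_round_trip(self, tmp_path):
        model = toy_chain_model(3, 1.2, 2.0)
        path = tmp_path / "chain.xml"
        export_sbml(model, path)
        back = import_sbml(path)
        assert back.content_hash() == model.content_hash()


class TestForeignDocuments:
    def test_unknown_kinetic_law_rejected(self, tmp_path):
        import libsbml
        doc = libsbml.SBMLDocument(3, 2)
        m = doc.createModel()
        m.setId("weird")
        c = m.createCompartment(); c.setId("cytosol"); c.setConstant(True)
        c.setSize(1.0); c.setSpatialDimensions(3)
        for sid in ("x", "y"):
            s = m.createSpecies(); s.setId(sid); s.setCompartment("cytosol")
            s.setInitialConcentration(1.0); s.setBoundaryCondition(False)
            s.setConstant(False); s.setHasOnlySubstanceUnits(False)
        r = m.createReaction(); r.setId("rx"); r.setReversible(False)
        ref = r.createReactant(); ref.setSpecies("x"); ref.setStoichiometry(1.0)
        ref.setConstant(True)
        ref = r.createProduct(); ref.setSpecies("y"); ref.setStoichiometry(1.0)
        ref.setConstant(True)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("alpha * x^3 / (beta + x^3)"))
        for pname in ("alpha", "beta"):
            lp = kl.createLocalParameter(); lp.setId(pname); lp.setValue(1.0)
        path = tmp_path / "foreign.xml"
        libsbml.writeSBMLToFile(doc, str(path))
        with pytest.raises(UnsupportedRateLawError):
            import_sbml(path)

    def test_foreign_mm_signature_accepted(self, tmp_path):
        import libsbml
        doc = libsbml.SBMLDocument(3, 2)
        m = doc.createModel(); m.setId("plain_mm")
        c = m.createCompartment(); c.setId("cytosol"); c.setConstant(True)
        c.setSize(1.0); c.setSpatialDimensions(3)
        for sid, init in (("s", 2.0), ("p", 0.0)):
            sp = m.createSpecies(); sp.setId(sid); sp.setCompartment("cytosol")
            sp.setInitialConcentration(init); sp.setBoundaryCondition(False)
            sp.setConstant(False); sp.setHasOnlySubstanceUnits(False)
        r = m.createReaction(); r.setId("rx"); r.setReversible(False)
        ref = r.createReactant(); ref.setSpecies("s"); ref.setStoichiometry(1.0)
        ref.setConstant(True)
        ref = r.createProduct(); ref.setSpecies("p"); ref.setStoichiometry(1.0)
        ref.setConstant(True)
        kl = r.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("vmax * s / (km_a + s)"))
        for pname, val in (("vmax", 1.0), ("km_a", 0.5)):
            lp = kl.createLocalParameter(); lp.setId(pname); lp.setValue(val)
        path = tmp_path / "mm.xml"
        libsbml.writeSBMLToFile(doc, str(path))
        model = import_sbml(path)
        assert model.get_reaction("rx").rate_law.kind == "michaelis_menten"
        traj = ck.simulate(model, t_end=5.0, dt_out=0.5)
        assert traj.final("p") > 0.5

    def test_unreadable_document(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<not-sbml/>")
        with pytest.raises(SBMLReadError):
            import_sbml(path)
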