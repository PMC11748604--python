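import random

import pytest

import oracles
from conftest import FIXTURE_EVALUE
from coretree._errors import ConfigurationError, NoLociError
from coretree.extract import CodingSequence, GenomeRecord
from coretree.screen import (
    PresenceMatrix,
    Status,
    find_singletons,
    screen_loci,
    select_loci,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length=80):
    return "".join(rng.choice(AA) for _ in range(length))


def _mutate(rng, seq, fraction=0.05):
    out = list(seq)
    for i in rng.sample(range(len(seq)), max(1, int(fraction * len(seq)))):
        out[i] = rng.choice(AA.replace(out[i], ""))
    return "".join(out)


def _genome(genome_id, proteins):
    return GenomeRecord(
        genome_id=genome_id,
        sequences=[CodingSequence(genome_id, k, v) for k, v in proteins.items()],
    )


class TestFindSingletons:
    def test_all_unrelated_are_singletons(self, backend):
        rng = random.Random(0)
        proteins = {k: _random_protein(rng) for k in "abc"}
        db = backend.build_database(_genome("g", proteins))
        assert find_singletons(db, backend=backend) == {"g|a", "g|b", "g|c"}

    def test_duplicates_excluded(self, backend):
        rng = random.Random(1)
        a = _random_protein(rng)
        proteins = {"a": a, "a2": a, "b": _random_protein(rng)}
        db = backend.build_database(_genome("g", proteins))
        assert find_singletons(db, backend=backend) == {"g|b"}

    def test_matches_exhaustive_oracle_with_planted_duplicates(self, backend):
        rng = random.Random(2)
        proteins = {f"p{i}": _random_protein(rng) for i in range(6)}
        proteins["d1a"], proteins["d1b"] = (
            (s := _random_protein(rng)), _mutate(rng, s)
        )
        proteins["d2a"], proteins["d2b"] = (
            (s := _random_protein(rng)), _mutate(rng, s)
        )
        db = backend.build_database(_genome("g", proteins))
        got = find_singletons(db, 1e-3, backend=backend)
        want = {
            f"g|{x}"
            for x in oracles.singletons_by_exhaustive_search(proteins, 1e-3)
        }
        assert got == want == {f"g|p{i}" for i in range(6)}


@pytest.fixture(scope="module")
def screened(small_fixture, backend):
    _, genomes, truth = small_fixture
    dbs = {g: backend.build_database(genomes[g]) for g in genomes}
    singletons = find_singletons(dbs["g00"], FIXTURE_EVALUE, backend=backend)
    matrix = screen_loci(singletons, genomes, dbs, FIXTURE_EVALUE, backend=backend)
    return genomes, dbs, truth, matrix


class TestScreenLoci:
    def test_core_rows_all_singleton(self, screened):
        _, _, truth, matrix = screened
        for locus in truth.core_loci("g00"):
            assert all(
                matrix.status[(locus, g)] is Status.SINGLETON for g in matrix.genomes
            ), locus

    def test_duplicated_family_rows_contain_multi(self, screened):
        _, _, _, matrix = screened
        dup_rows = [l for l in matrix.loci if "DUPF" in l]
        assert dup_rows
        for locus in dup_rows:
            assert matrix.has_multi(locus), locus

    def test_accessory_rows_contain_absent(self, screened):
        _, _, _, matrix = screened
        acc_rows = [l for l in matrix.loci if "ACCS" in l]
        assert acc_rows
        for locus in acc_rows:
            assert any(
                matrix.status[(locus, g)] is Status.ABSENT for g in matrix.genomes
            ), locus

    def test_status_defined_everywhere_and_seed_singleton(self, screened):
        _, _, _, matrix = screened
        for locus in matrix.loci:
            for g in matrix.genomes:
                status = matrix.status[(locus, g)]
                assert isinstance(status, Status)
                assert (status is Status.SINGLETON) == (
                    (locus, g) in matrix.best_match
                )
            assert matrix.status[(locus, "g00")] is Status.SINGLETON

    def test_selected_loci_are_reciprocal_best_hits(self, screened, backend):
        """Every (seed locus, best match) pair is an RBH: searching the
        match back against the seed genome hits exactly the seed locus."""
        genomes, dbs, _, matrix = screened
        selection = select_loci(matrix, 100.0)
        for locus in selection.loci:
            _, seed_locus = locus.split("|", 1)
            for genome_id, member in selection.members[locus].items():
                query = CodingSequence(
                    genome_id, member, dbs[genome_id].entries[member]
                )
                back = backend.search(query, dbs["g00"], FIXTURE_EVALUE)
                assert [h.subject_id for h in back] == [f"g00|{seed_locus}"]

    def test_seed_missing_from_dbs_is_configuration_error(self, screened, backend):
        genomes, dbs, _, _ = screened
        with pytest.raises(ConfigurationError):
            screen_loci({"zz|x"}, genomes, dbs, backend=backend)

    def test_tsv_report(self, screened, tmp_path):
        _, _, _, matrix = screened
        path = matrix.to_tsv(tmp_path / "m.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[1:] == matrix.genomes
        assert len(lines) == 1 + len(matrix.loci)


def _matrix(rows, genomes):
    """rows: locus -> string of S/M/A per genome."""
    status, best = {}, {}
    for locus, cells in rows.items():
        for genome, cell in zip(genomes, cells):
            status[(locus, genome)] = Status(cell)
            if cell == "S":
                best[(locus, genome)] = f"{genome}_{locus}"
    return PresenceMatrix(
        loci=sorted(rows), genomes=list(genomes), status=status,
        best_match=best, seed_genome=genomes[0],
    )


class TestSelectLoci:
    def test_all_singleton_rows_selected(self):
        m = _matrix({f"L{i}": "SSSS" for i in range(5)}, list("abcd"))
        assert select_loci(m, 100.0).loci == sorted(f"L{i}" for i in range(5))

    def test_maxloci_lexicographic_truncation(self):
        m = _matrix({f"L{i}": "SSSS" for i in range(5)}, list("abcd"))
        assert select_loci(m, 100.0, maxloci=3).loci == ["L0", "L1", "L2"]

    def test_maxloci_seeded_sample_is_deterministic(self):
        m = _matrix({f"L{i}": "SSSS" for i in range(8)}, list("abcd"))
        first = select_loci(m, 100.0, maxloci=3, rng_seed=5).loci
        second = select_loci(m, 100.0, maxloci=3, rng_seed=5).loci
        assert first == second
        assert len(first) == 3 and first == sorted(first)

    def test_presence_threshold_ceiling_arithmetic(self):
        # 10 genomes, singleton in 8, absent in 2: ceil(0.8*10)=8 -> kept,
        # ceil(0.9*10)=9 -> rejected
        genomes = [f"g{i}" for i in range(10)]
        m = _matrix({"L": "S" * 8 + "A" * 2}, genomes)
        assert select_loci(m, 80.0).loci == ["L"]
        with pytest.raises(NoLociError):
            select_loci(m, 90.0)

    def test_multi_disqualifies_even_at_low_presence(self):
        m = _matrix({"L": "SSSM", "K": "SSSA"}, list("abcd"))
        assert select_loci(m, 50.0).loci == ["K"]

    def test_zero_selected_is_hard_error(self):
        m = _matrix({"L": "SSMM"}, list("abcd"))
        with pytest.raises(NoLociError, match="presence"):
            select_loci(m, 100.0)

    def test_invalid_thresholds(self):
        m = _matrix({"L": "SSSS"}, list("abcd"))
        for bad in (0, -5, 101):
            with pytest.raises(ValueError):
                select_loci(m, bad)
        with pytest.raises(ValueError):
            select_loci(m, 100.0, maxloci=0)

    def test_monotonicity_in_presence(self):
        rng = random.Random(9)
        genomes = [f"g{i}" for i in range(6)]
        rows = {
            f"L{i}": "S" + "".join(rng.choice("SSA") for _ in range(5))
            for i in range(30)
        }
        m = _matrix(rows, genomes)

        def n_selected(p):
            try:
                return len(select_loci(m, p))
            except NoLociError:
                return 0

        thresholds = [10, 25, 40, 50, 60, 75, 90, 100]
        counts = [n_selected(p) for p in thresholds]
        assert counts == sorted(counts, reverse=True)

    def test_maxloci_yields_min_of_n_and_available(self):
        m = _matrix({f"L{i}": "SSSS" for i in range(4)}, list("abcd"))
        for n in (1, 2, 4, 10):
            assert len(select_loci(m, 100.0, maxloci=n)) == min(n, 4)
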