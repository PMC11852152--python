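"""Prompt assembly, token estimation, backends, rule-based corrections."""

import pytest

from promptner import (
    BudgetError,
    CorrectionRule,
    DEFAULT_CORRECTION_RULES,
    DEFAULT_TRANSITION,
    IdentityBackend,
    InvariantError,
    PromptSpec,
    ReplayBackend,
    TransportError,
    annotate_report,
    apply_corrections,
    build_prompt,
    default_prompt_spec,
    estimate_tokens,
    normalize_quotes,
    parse_markup,
)
from promptner.prompting import PromptWarning, extract_target


class TestBuildPrompt:
    def test_transition_immediately_precedes_target(self):
        spec = default_prompt_spec("REPORT BODY")
        prompt = build_prompt(spec)
        assert f"{DEFAULT_TRANSITION}\nREPORT BODY" in prompt

    def test_component_order(self):
        spec = default_prompt_spec("the target")
        prompt = build_prompt(spec)
        positions = [
            prompt.index(spec.instructions[:30]),
            prompt.index(spec.shots[0].input_text),
            prompt.index(DEFAULT_TRANSITION),
            prompt.index("the target"),
            prompt.index(spec.control_phrases[0]),
        ]
        assert positions == sorted(positions)

    def test_control_phrases_close_the_prompt(self):
        spec = default_prompt_spec("x")
        prompt = build_prompt(spec)
        tail = prompt.rstrip()
        assert tail.endswith("###Why didn’t you output in a code snippet window?")
        assert "###Do not forget to output in a code snippet window." in tail

    def test_zero_shot_mode(self):
        spec = PromptSpec(instructions="Annotate.", shots=(), target_report="r")
        prompt = build_prompt(spec)
        assert "Example" not in prompt
        assert DEFAULT_TRANSITION in prompt

    def test_deterministic(self):
        a = build_prompt(default_prompt_spec("same"))
        b = build_prompt(default_prompt_spec("same"))
        assert a == b

    def test_budget_overflow(self):
        spec = default_prompt_spec("target")
        with pytest.raises(BudgetError, match="overflow"):
            build_prompt(spec, budget=10)

    def test_token_estimate_populated(self):
        spec = default_prompt_spec("target")
        prompt = build_prompt(spec)
        assert spec.token_estimate == estimate_tokens(prompt)

    def test_packaged_shots_round_trip(self):
        for shot in default_prompt_spec("x").shots:
            shot.validate()
            doc = parse_markup(shot.output_markup)
            assert doc.spans  # every packaged example demonstrates markup


class TestSpecFromConfig:
    def test_components_loaded_relative_to_config(self, tmp_path):
        from promptner import spec_from_config

        (tmp_path / "inst.txt").write_text("Custom instructions.\n", encoding="utf-8")
        (tmp_path / "shots.jsonl").write_text(
            '{"input": "a mass", "output": "a <span class=\\"OBS-P\\">mass</span>"}\n',
            encoding="utf-8",
        )
        (tmp_path / "prompt.cfg").write_text(
            "# components\ninstructions = inst.txt\nshots = shots.jsonl\n"
            "budget = 5000\n",
            encoding="utf-8",
        )
        spec, budget, rules = spec_from_config(tmp_path / "prompt.cfg", "target")
        assert spec.instructions.startswith("Custom instructions.")
        assert len(spec.shots) == 1 and spec.shots[0].input_text == "a mass"
        assert budget == 5000
        assert rules == DEFAULT_CORRECTION_RULES
        prompt = build_prompt(spec, budget=budget)
        assert "Custom instructions." in prompt
        assert prompt.rstrip().endswith(
            "###Why didn’t you output in a code snippet window?"
        )

    def test_unknown_key_rejected(self, tmp_path):
        from promptner import spec_from_config

        cfg = tmp_path / "bad.cfg"
        cfg.write_text("nonsense = x\n", encoding="utf-8")
        with pytest.raises(InvariantError, match="nonsense"):
            spec_from_config(cfg, "t")


class TestShuffleShots:
    def test_seeded_shuffle_reproducible_permutation(self):
        from promptner import shuffle_shots

        shots = default_prompt_spec("x").shots
        a = shuffle_shots(shots, seed=5)
        b = shuffle_shots(shots, seed=5)
        assert a == b
        assert sorted(a, key=lambda s: s.input_text) == sorted(
            shots, key=lambda s: s.input_text
        )
        assert shuffle_shots(shots, seed=6) != a  # different seed reorders


class TestEstimateTokens:
    def test_empty(self):
        assert estimate_tokens("") == 0

    def test_heuristic_quarter(self):
        assert estimate_tokens("a" * 40) == 10
        assert estimate_tokens("a" * 41) == 11

    def test_pluggable_tokenizer(self):
        assert estimate_tokens("one two three", lambda t: len(t.split())) == 3


class TestBackends:
    def test_identity_backend_is_divergence_free(self):
        spec = default_prompt_spec("plain report text")
        prompt = build_prompt(spec)
        backend = IdentityBackend(control_phrases=spec.control_phrases)
        markup = annotate_report(prompt, backend, target_text="plain report text")
        assert parse_markup(markup).spans == ()
        assert parse_markup(markup).text == "plain report text"

    def test_replay_backend_from_dir(self, tmp_path):
        (tmp_path / "r1.input.txt").write_text("the report\n", encoding="utf-8")
        (tmp_path / "r1.response.txt").write_text(
            '```\n<span class="IMP">the report</span>\n```\n', encoding="utf-8"
        )
        backend = ReplayBackend.from_dir(tmp_path)
        prompt = build_prompt(default_prompt_spec("the report"))
        markup = annotate_report(prompt, backend)
        assert parse_markup(markup).spans[0].label == "IMP"

    def test_replay_backend_unknown_target(self):
        backend = ReplayBackend({"known": "```\nknown\n```"})
        with pytest.raises(TransportError):
            annotate_report("unrelated prompt", backend, retries=0)

    def test_retries_then_transport_error(self):
        calls = []

        def flaky(prompt):
            calls.append(1)
            raise ConnectionError("down")

        with pytest.raises(TransportError, match="3 attempt"):
            annotate_report("p", flaky, retries=2)
        assert len(calls) == 3

    def test_divergence_warning(self):
        backend = lambda prompt: "```\ncompletely different text\n```"  # noqa: E731
        spec = default_prompt_spec("original")
        with pytest.warns(PromptWarning, match="different text than the target"):
            annotate_report(build_prompt(spec), backend, target_text="original")

    def test_extract_target_round_trip(self):
        spec = default_prompt_spec("line one\nline two")
        prompt = build_prompt(spec)
        assert (
            extract_target(prompt, DEFAULT_TRANSITION, spec.control_phrases)
            == "line one\nline two"
        )


class TestCorrections:
    def test_default_rule_strips_boilerplate_span(self):
        wrong = (
            "<span class = “ANAT”>Sol memenin</span> MLO ve CC "
            "mammogramları elde olunmuştur"
        )
        fixed = apply_corrections(wrong)
        assert fixed == "Sol memenin MLO ve CC mammogramları elde olunmuştur"

    def test_straight_quote_variant_also_matches(self):
        wrong = (
            '<span class = "ANAT">Sağ memenin</span> MLO ve CC '
            "mammogramları elde olunmuştur"
        )
        assert apply_corrections(wrong).startswith("Sağ memenin MLO")

    def test_untouched_when_no_rule_matches(self):
        text = '<span class="ANAT">sağ meme</span> normal'
        assert apply_corrections(text) == text

    def test_idempotent(self):
        wrong = (
            "<span class = “ANAT”>SOL</span> MAMMOGRAFİ RAPORUNUN DA "
            "OKUNMASI ÖNERİLİR"
        )
        once = apply_corrections(wrong)
        assert apply_corrections(once) == once

    def test_user_rules_appended(self):
        rules = DEFAULT_CORRECTION_RULES + (CorrectionRule("abc", "xyz"),)
        assert apply_corrections("say abc", rules) == "say xyz"

    def test_rule_validation(self):
        with pytest.raises(InvariantError):
            CorrectionRule("", "x")
        with pytest.raises(InvariantError):
            CorrectionRule("same", "same")

    def test_stripped_length_changes_only_by_tag_removal(self):
        wrong = (
            "<span class = “ANAT”>SAĞ</span> MAMMOGRAFİ RAPORUNUN DA "
            "OKUNMASI ÖNERİLİR"
        )
        before = parse_markup(normalize_quotes(wrong)).text
        after = apply_corrections(wrong)
        assert parse_markup(after).text == before
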