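# Default ConText/NegEx-style trigger lexicon.
# Each phrase opens a scope in its direction (forward = tokens after it,
# backward = tokens before it) for one context dimension.  Scopes run to
# the sentence boundary, a terminator, or `scope_limit` tokens.
scope_limit: 8
terminators:
  - but
  - however
  - although
  - though
  - except
  - apart from
  - aside from
  - nevertheless
triggers:
  negation:
    negated:
      forward:
        - "no"
        - "not"
        - denies
        - denied
        - denying
        - without
        - no evidence of
        - no evidence for
        - no sign of
        - no signs of
        - no symptoms of
        - no indication of
        - no complaints of
        - no history of
        - no further
        - negative for
        - free of
        - absence of
        - rules out
        - cannot identify
        - fails to reveal
        - failed to reveal
        - never had
        - never developed
        - never experienced
        - resolved without
        - with no
        - declines any
        - doubt
        - unremarkable for
      backward:
        - unlikely
        - was ruled out
        - is ruled out
        - has been ruled out
        - were ruled out
        - ruled out
        - not present
        - not demonstrated
        - not seen
        - not detected
  temporality:
    historical:
      forward:
        - history of
        - known history of
        - past medical history of
        - past history of
        - h/o
        - hx of
        - previous
        - prior
        - previously
        - former
        - longstanding
        - status post
        - in the past
        - childhood
      backward:
        - years ago
        - in childhood
        - as a child
        - in the remote past
    hypothetical:
      forward:
        - "if"
        - risk of
        - at risk for
        - at risk of
        - concern for
        - possible
        - possibly
        - suspected
        - rule out
        - watch for
        - should
        - in case of
        - may develop
        - could develop
  experiencer:
    other:
      forward:
        - father
        - father's
        - mother
        - mother's
        - brother
        - sister
        - uncle
        - aunt
        - grandfather
        - grandmother
        - wife
        - husband
        - son
        - daughter
        - family history of
        - family member with
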