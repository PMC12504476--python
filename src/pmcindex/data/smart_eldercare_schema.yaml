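# The 9-primary / 33-secondary indicator system used to evaluate China's
# smart older-adults-care policies. Each secondary variable is a yes/no
# criterion judged against the policy text (1 = present).
name: smart-older-adults-care
primaries:
  - index: 1
    label: Policy Nature
    secondaries:
      - id: X11
        label: Supervision
        criterion: Does the policy involve supervision of development? 1 if yes, 0 if not.
      - id: X12
        label: Prediction
        criterion: Does the policy describe expected future development outcomes? 1 if yes, 0 if not.
      - id: X13
        label: Guidance
        criterion: Does the policy state guiding goals for development? 1 if yes, 0 if not.
  - index: 2
    label: Policy Area
    secondaries:
      - id: X21
        label: Economy
        criterion: Does the policy touch the economic area? 1 if yes, 0 if not.
      - id: X22
        label: Medicine
        criterion: Does the policy touch the medical area? 1 if yes, 0 if not.
      - id: X23
        label: Technology
        criterion: Does the policy touch the technology area? 1 if yes, 0 if not.
  - index: 3
    label: Policy Timeliness
    secondaries:
      - id: X31
        label: Long term
        criterion: Does the policy cover a horizon of more than 5 years? 1 if yes, 0 if not.
      - id: X32
        label: Mid-term
        criterion: Does the policy cover a 3-5 year horizon? 1 if yes, 0 if not.
      - id: X33
        label: Short-term
        criterion: Does the policy cover a horizon of up to 3 years? 1 if yes, 0 if not.
  - index: 4
    label: Policy Aim
    secondaries:
      - id: X41
        label: Product development
        criterion: Does the aim include developing products that meet older adults' needs? 1 if yes, 0 if not.
      - id: X42
        label: Publicity and Promotion
        criterion: Does the aim include publicising and promoting older-adults services? 1 if yes, 0 if not.
      - id: X43
        label: Service Supply Optimization
        criterion: Does the aim include optimising service provision? 1 if yes, 0 if not.
  - index: 5
    label: Policy Content
    secondaries:
      - id: X51
        label: Application Pilot
        criterion: Does the content include application pilots? 1 if yes, 0 if not.
      - id: X52
        label: Technical Training
        criterion: Does the content include technical training or education for older adults? 1 if yes, 0 if not.
      - id: X53
        label: Government Subsidy
        criterion: Does the content include government subsidies? 1 if yes, 0 if not.
      - id: X54
        label: Smart Device
        criterion: Does the content include smart devices? 1 if yes, 0 if not.
      - id: X55
        label: Network Security
        criterion: Does the content include network security? 1 if yes, 0 if not.
  - index: 6
    label: Policy Object
    secondaries:
      - id: X61
        label: Government
        criterion: Do the policy objects include government? 1 if yes, 0 if not.
      - id: X62
        label: Business Unit
        criterion: Do the policy objects include business units? 1 if yes, 0 if not.
      - id: X63
        label: Community
        criterion: Do the policy objects include communities? 1 if yes, 0 if not.
      - id: X64
        label: Household
        criterion: Do the policy objects include households? 1 if yes, 0 if not.
  - index: 7
    label: Policy Evaluation
    secondaries:
      - id: X71
        label: Sufficient Basis
        criterion: Is the policy basis sufficient? 1 if yes, 0 if not.
      - id: X72
        label: Planning Details
        criterion: Is the policy planned in detail? 1 if yes, 0 if not.
      - id: X73
        label: Scheme Science
        criterion: Is the policy scheme scientific? 1 if yes, 0 if not.
  - index: 8
    label: Policy Measure
    secondaries:
      - id: X81
        label: Institutional Reform
        criterion: Do the measures include institutional reform building specialised older-adults institutions? 1 if yes, 0 if not.
      - id: X82
        label: Financial Support
        criterion: Do the measures include financial support? 1 if yes, 0 if not.
      - id: X83
        label: Cultivation of Talent
        criterion: Do the measures include talent training? 1 if yes, 0 if not.
      - id: X84
        label: Legal Safeguards
        criterion: Do the measures include legal safeguards? 1 if yes, 0 if not.
      - id: X85
        label: Assessment and Evaluation
        criterion: Do the measures include assessment and evaluation? 1 if yes, 0 if not.
  - index: 9
    label: Policy Tool
    secondaries:
      - id: X91
        label: Compulsory Type
        criterion: Does the policy specify prohibited or permitted behaviours? 1 if yes, 0 if not.
      - id: X92
        label: Innovative Type
        criterion: Does the policy integrate technological, institutional or industrial innovation? 1 if yes, 0 if not.
      - id: X93
        label: Market Type
        criterion: Does the policy give play to market resource allocation? 1 if yes, 0 if not.
      - id: X94
        label: Cooperative Type
        criterion: Does the policy involve international cooperation? 1 if yes, 0 if not.
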