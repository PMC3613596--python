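# Three-agent myocardial-infarction consultation case.
#
# A records agent announces an elderly patient with chest pain; the
# cardiology lead infers a possible MI, raises management sub-goals,
# weighs two drugs and provisionally prefers aspirin; the drug-safety
# specialist, asked to confirm, discovers the patient has gastritis,
# which aspirin exacerbates, and advises clopidogrel; challenged for its
# rationale, it explains, and the lead commits firm to clopidogrel.
format_version: 1

concepts:
  - {id: abnormal_state}
  - {id: disease, parents: [abnormal_state], properties: [has_symptoms]}
  - {id: heart_attack, parents: [disease]}
  - {id: myocardial_infarction, parents: [heart_attack]}
  - {id: gastritis, parents: [disease]}
  - {id: treatment}
  - {id: drug, parents: [treatment]}
  - id: aspirin
    parents: [drug]
    properties: [easily_available, modestly_priced]
  - id: clopidogrel
    parents: [drug]
    properties: [easily_available]
  - {id: condition_goal}
  - {id: analgesia, parents: [condition_goal]}
  - {id: clot_prevention, parents: [condition_goal]}
  - {id: gastric_protection, parents: [condition_goal]}

relations:
  vocabulary: [effective_for, exacerbates, causes]
  assertions:
    - [aspirin, effective_for, analgesia]
    - [aspirin, effective_for, clot_prevention]
    - [clopidogrel, effective_for, analgesia]
    - [clopidogrel, effective_for, clot_prevention]

rules:
  - id: b_heart_attack
    kind: belief
    when: [complaint, chest_pain]
    then: [[possible, heart_attack]]
  - id: b_mi
    kind: belief
    when: {all: [[possible, heart_attack], [patient, elderly]]}
    then: [[possible, myocardial_infarction]]
  - id: g_manage_mi
    kind: goal
    when: [possible, myocardial_infarction]
    goal:
      name: manage_mi
      condition: [myocardial_infarction, managed]
      stakes: high
      priority: 5
  - id: g_mi_subgoals
    kind: goal
    when: ["goal:manage_mi", active]
    goals:
      - name: prevent_clotting
        condition: [clotting, prevented]
        parent: manage_mi
        priority: 4
      - name: prevent_pain
        condition: [pain, prevented]
        parent: manage_mi
        priority: 4
  - id: g_choose_drug
    kind: goal
    when: {all: [["goal:prevent_clotting", active], ["goal:prevent_pain", active]]}
    goal:
      name: choose_mi_drug
      condition: [mi_drug, chosen]
      stakes: high
      priority: 6
      parent: manage_mi
      kind: decide
      targets: [analgesia, clot_prevention]
  - id: c_mi_drugs
    kind: candidate
    for_goal: choose_mi_drug
    when: {all: []}
    options: [aspirin, clopidogrel]

schemas:
  - id: efficacy_pro
    polarity: pro
    strength: 1
    condition:
      - relation: ["?candidate", effective_for, "?condition"]
      - goal_target: "?condition"
  - id: availability_pro
    polarity: pro
    strength: 1
    condition:
      - property: ["?candidate", easily_available]
  - id: price_pro
    polarity: pro
    strength: 1
    condition:
      - property: ["?candidate", modestly_priced]

agents:
  records:
    role: records
    announce_to: cardio
    announce:
      - [patient, elderly]
      - [complaint, chest_pain]
    case:
      - [patient, elderly]
      - [complaint, chest_pain]
      - [has_condition, gastritis]
  cardio:
    role: lead
    consult: [safety]
  safety:
    role: specialist
    askable: {has_condition: records}
    partition:
      concepts:
        - id: proton_pump_inhibitor
          parents: [drug]
          properties: [easily_available]
      relations:
        vocabulary: [effective_for, exacerbates]
        assertions:
          - [aspirin, exacerbates, gastritis]
          - [proton_pump_inhibitor, effective_for, gastric_protection]
      rules:
        - id: c_safety_options
          kind: candidate
          for_goal: choose_mi_drug
          when: {all: []}
          options: [proton_pump_inhibitor]
      schemas:
        - id: exacerbation_con
          polarity: con
          strength: 2
          condition:
            - relation: ["?candidate", exacerbates, "?condition"]
            - belief: [has_condition, "?condition"]
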