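HED version="2.0"

'''Event''' [The experimental or real-world event this annotation describes]
* Category {required, childRequired} [Required broad classification of the event]
** Initial context
** Participant response
** Technical error
** Participant failure
** Environmental
** Experimental stimulus
** Experimental procedure
** Incidental
** Miscellaneous
** Experimental control
* Label {required, childRequired} [Required short study-local identifier for events of this type]
** # {takesValue} [A short (less than 20 character) identifier]
* Description {childRequired, unique, recommended} [Recommended human-readable description of the event]
** # {takesValue} [Free-text description]

'''Item''' {extensionAllowed} [A thing present in or relevant to the event]
* ID {predicateType=property} [Identifying number of the item]
** # {takesValue, isNumeric}
* Group ID {predicateType=property} [Identifying number of the item's group]
** # {takesValue, isNumeric}
* 2D shape
** Ellipse
*** Circle
** Rectangle
*** Square
** Star
* Object
** Person
** Animal
*** Fish
** Furniture
*** Chair
** Vehicle
*** Car

'''Sensory presentation''' [How an item is presented to the senses]
* Visual
** Rendering type
*** Screen
**** 2D
**** 3D
* Auditory

'''Attribute''' [Descriptive elements; may modify any part of the hierarchy]
* Visual
** Color
*** Red
*** Green
*** Blue
* Fixation point
* Location
** Screen
*** Center
*** Left
*** Right
*** Top
*** Bottom
* Presentation fraction [Fraction of stimulus stream occupied by this stimulus class]
** # {takesValue, isNumeric}
* Vehicle Control
** Perturb
* Onset
* Offset
* Duration [How long the event persists]
** # {takesValue, unitClass=time}

'''Action''' [An action by the participant or another agent]
* Type
** Eat
** Walk
** Button press

'''Participant''' [The participant and the event's (intended) effect on them]
* ID {predicateType=property, default=1} [Participant number within the study]
** # {takesValue, isNumeric}
* Role
* State
** Awake
** Drowsy
* Effect
** Visual
** Auditory
** Cognitive
*** Target
*** Oddball
*** Threat
*** Reward [Reward value of the event]
**** # {takesValue, unitClass=currency}

'''Experiment context''' [Where and under what conditions the experiment takes place]
* Indoors
* Outdoors

'''Paradigm''' [The experimental paradigm]
* Visual oddball paradigm
* N-back paradigm

'''HED''' [Metadata about the annotation itself]
* # {takesValue} [Schema version used]

'''Custom''' {extensionAllowed} [Free extension area for study-specific tags]

== Unit classes ==
* time {default=s} [s, ms]
* physicalLength {default=m} [m, cm, mm]
* angle {default=radian} [degree, radian]
* frequency {default=Hz} [Hz]
* area {default=m^2} [m^2]
* volume {default=m^3} [m^3]
* currency {default=$} [$]
* velocity {default=m-per-s} [m-per-s]
* jerk {default=m-per-s^3} [m-per-s^3]
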