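"""Template banks for the synthetic transcript generator.

Three dialogue families use deliberately disjoint topic vocabularies so that
lexical classifiers and TF-IDF similarity have a learnable signal:

* activity vocabulary — nouns/settings used by action recommendations and by
  the review dialogues that revisit them;
* event vocabulary — client-initiated future plans that are *not* therapist
  recommendations (the stage-2 negative class);
* filler vocabulary — general therapeutic content with no future orientation.

Padding words are shared across families on purpose: TF-IDF must learn the
template/topic words, not incidental function words.
"""

from __future__ import annotations

# 60 activity nouns; a client's recommended activities cycle through a
# per-client permutation, so two consecutive sessions never repeat a noun and
# a review dialogue is lexically tied to exactly one prior recommendation.
ACTIVITY_NOUNS = [
    "cooking", "jogging", "journaling", "meditation", "yoga", "swimming",
    "gardening", "painting", "sketching", "knitting", "cycling", "hiking",
    "stretching", "budgeting", "volunteering", "photography", "pottery",
    "baking", "birdwatching", "chess", "dancing", "singing", "drumming",
    "guitar", "piano", "origami", "calligraphy", "woodworking", "sculpting",
    "rowing", "climbing", "skating", "bowling", "archery", "fishing",
    "camping", "stargazing", "scrapbooking", "quilting", "embroidery",
    "crosswords", "sudoku", "juggling", "pilates", "boxing", "surfing",
    "kayaking", "tennis", "badminton", "basketball", "puzzles", "carpentry",
    "brewing", "composting", "beekeeping", "astronomy", "geocaching",
    "foraging", "whittling", "mosaics",
]

ACTIVITY_SETTINGS = [
    "morning", "evening", "weekend", "outdoor", "indoor", "neighborhood",
    "community", "beginner", "gentle", "daily",
]

# Upcoming-event nouns for "future plan" dialogues that are not action
# recommendations (the client brings them up; the therapist only explores).
EVENT_NOUNS = [
    "wedding", "interview", "reunion", "graduation", "relocation",
    "conference", "recital", "tournament", "inspection", "ceremony",
    "deadline", "presentation", "audit", "festival", "anniversary",
    "hearing", "enrollment", "banquet", "orientation", "fundraiser",
]

# Filler topics: present- or past-focused therapeutic content, disjoint from
# the activity and event banks.
FILLER_TOPICS = [
    "sleep", "appetite", "childhood", "memories", "dreams", "tension",
    "worries", "sadness", "irritability", "loneliness", "fatigue",
    "concentration", "self-esteem", "grief", "arguments", "silence",
    "crying", "numbness", "restlessness", "guilt",
]

# Neutral padding words drawn for every dialogue kind.
PAD_WORDS = [
    "really", "perhaps", "together", "sometimes", "lately", "honestly",
    "gradually", "certainly", "somehow", "meanwhile", "often", "rarely",
    "quietly", "slowly", "carefully", "openly", "gently", "steadily",
    "clearly", "actually", "mostly", "nearly", "simply", "usually",
    "frankly", "truly", "briefly", "broadly", "deeply", "early",
]

# Recommendation-cue lexicon: words characteristic of a therapist making an
# action recommendation. Shared with detect.REC_CUE_LEXICON via import.
REC_CUES = [
    "recommend", "suggest", "try", "practice", "schedule", "homework",
    "assignment", "commit", "goal", "agree", "advice",
]

# Sentence templates. "{p}" is the activity phrase ("<setting> <noun> routine"),
# "{e}" an event noun, "{f}" a filler topic. Each backbone is a list of
# positions; each position offers several phrasing variants (speaker,
# sentence), one drawn per dialogue. Varying the boilerplate keeps TF-IDF
# similarity anchored on the activity tokens rather than on a fixed template,
# mirroring how two recommendations by the same therapist share topic, not
# wording.

RECOMMENDATION_BACKBONE = [
    [("T", "I would recommend that you try a {p} this coming week and notice how it affects your mood."),
     ("T", "One thing I want to suggest is starting a {p} before we meet again."),
     ("T", "It could help to practice a {p} between now and our next conversation."),
     ("T", "My advice would be to experiment with a {p} and see what shifts for you.")],
    [("C", "I suppose I could give the {p} a chance if it helps."),
     ("C", "Honestly a {p} sounds doable even on my harder days."),
     ("C", "I am willing to attempt the {p} although mornings are rough."),
     ("C", "Maybe the {p} is worth a shot since nothing else has stuck.")],
    [("T", "Let us agree that the {p} becomes your homework and we can set a small goal around it."),
     ("T", "We can treat the {p} as a gentle assignment rather than an obligation."),
     ("T", "Think of the {p} as one small goal you are choosing for yourself."),
     ("T", "Let us make the {p} something you commit to loosely, without pressure.")],
    [("C", "Alright, I will commit to the {p} and tell you how it went."),
     ("C", "Fine, I can pencil in the {p} a couple of times."),
     ("C", "I will see whether the {p} fits into my week somewhere."),
     ("C", "Okay, the {p} goes on my list and we can talk about it later.")],
    [("T", "I suggest you schedule the {p} for a time of day when your energy is highest."),
     ("T", "Try anchoring the {p} to something you already do every day."),
     ("T", "You might practice the {p} in short stretches at first."),
     ("T", "Whatever pace you pick for the {p}, keep it kind to yourself.")],
]

REVIEW_BACKBONE = [
    [("T", "Last session we discussed your plan to start a {p} and I wanted to hear how it went."),
     ("T", "Before anything else, how did the {p} from last time actually go?"),
     ("T", "When we last met you agreed to attempt a {p}, so tell me about it."),
     ("T", "I remember we ended last week with the {p}, and I am curious what happened.")],
    [("C", "The {p} actually went better than I expected once I got started."),
     ("C", "I only managed the {p} twice but it was something."),
     ("C", "Getting myself to do the {p} was the hardest part, then it flowed."),
     ("C", "I kept up the {p} most days, which surprised me.")],
    [("T", "What did you notice about your mood on the days you kept up the {p}?"),
     ("T", "Walk me through one moment during the {p} that stood out."),
     ("T", "Did anything get in the way of the {p} that we should plan around?"),
     ("T", "How did your body feel before and after the {p}?")],
    [("C", "On the days with the {p} I felt a little lighter and less stuck."),
     ("C", "After the {p} the evenings seemed less heavy somehow."),
     ("C", "Skipping the {p} made the difference obvious, oddly enough."),
     ("C", "The {p} gave the day a bit of shape, which I needed.")],
    [("T", "It sounds like revisiting the {p} from last time was worthwhile for you."),
     ("T", "Checking back in on the {p} tells us a lot about what works."),
     ("T", "We can build on the {p} now that you have tried it once."),
     ("T", "Following up on the {p} like this is exactly the continuity I hoped for.")],
]

PLAN_BACKBONE = [
    [("C", "There is a {e} coming up soon and I keep thinking about how it will go."),
     ("C", "Next month brings the {e} and my mind will not leave it alone."),
     ("C", "I found out the {e} is happening sooner than I thought."),
     ("C", "Everyone keeps asking me about the upcoming {e}.")],
    [("T", "Tell me what feels most uncertain about the upcoming {e}."),
     ("T", "When you picture the {e}, what comes up first?"),
     ("T", "What part of the {e} feels within your control?"),
     ("T", "How have you been preparing yourself for the {e}?")],
    [("C", "Mostly I worry that the {e} will not go the way everyone expects."),
     ("C", "I keep rehearsing the {e} in my head at night."),
     ("C", "Part of me wants to skip the {e} entirely."),
     ("C", "The {e} matters to people I care about, which raises the stakes.")],
    [("T", "What would getting through the {e} in a way you are proud of look like?"),
     ("T", "Suppose the {e} goes imperfectly, what would you still have?"),
     ("T", "Who could support you on the day of the {e}?"),
     ("T", "What has helped you before events like this {e}?")],
    [("C", "I imagine leaving the {e} feeling calm instead of drained."),
     ("C", "If the {e} goes alright I think something will loosen in me."),
     ("C", "I just want the {e} behind me so I can breathe."),
     ("C", "Maybe the {e} is a chance to show myself something.")],
]

FILLER_BACKBONE = [
    [("T", "You mentioned your {f} earlier and I am curious how that has been."),
     ("T", "Let us return to the {f} you brought up before."),
     ("T", "How has the {f} been sitting with you this past while?"),
     ("T", "I want to make room today for the {f} you described.")],
    [("C", "The {f} has been weighing on me more than I let on."),
     ("C", "Some nights the {f} takes over everything."),
     ("C", "I notice the {f} most when the house goes quiet."),
     ("C", "The {f} comes and goes without much warning.")],
    [("T", "When the {f} shows up, what do you notice in your body?"),
     ("T", "Where do you feel the {f} the most?"),
     ("T", "What tends to come right before the {f}?"),
     ("T", "How do you usually respond once the {f} starts?")],
    [("C", "Mostly the {f} leaves me tense and a bit withdrawn."),
     ("C", "The {f} makes me short with people I love."),
     ("C", "I go numb when the {f} peaks, honestly."),
     ("C", "The {f} drains whatever energy the day left me.")],
    [("T", "Staying with the {f} for a moment, what would you want to be different?"),
     ("T", "If the {f} eased even slightly, what would change first?"),
     ("T", "What has ever softened the {f}, even briefly?"),
     ("T", "We can keep gently watching how the {f} moves this week.")],
]

BACKBONES = {
    "recommendation": RECOMMENDATION_BACKBONE,
    "review": REVIEW_BACKBONE,
    "plan": PLAN_BACKBONE,
    "filler": FILLER_BACKBONE,
}

# Generic follow-up sentences used to extend dialogues to their word budget.
GENERIC_THERAPIST = [
    "Take a moment and tell me more about that.",
    "I hear you and I want to understand what that is like.",
    "What goes through your mind when that happens?",
    "That makes sense given everything you have described.",
    "Let us slow down and look at that together.",
]

GENERIC_CLIENT = [
    "It is hard to put into words but I will try.",
    "I had not thought about it that way before.",
    "Some days are easier than others to be honest.",
    "I keep going back and forth about it.",
    "Talking it through here does help a little.",
]
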