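{"note_id": "sample-symptom-1", "text": "Spot on lip is gone. Overall doing well. Has a runny nose it no fever or any other symptoms.", "authored_at": "2020-11-05T18:30:00", "modality": "voice_transcript", "author_id": "parent-01"}
{"note_id": "sample-symptom-2", "text": "[patient name] oxygen was still hanging out around 80 today...blood sugar is 127.", "authored_at": "2020-11-06T09:10:00", "modality": "voice_transcript", "author_id": "parent-02"}
{"note_id": "sample-med-1", "text": "Gave [patient name] 2 Benadryl at 6:00 am…[patient name] does not take his medicine after lunch.", "authored_at": "2020-11-07T07:45:00", "modality": "voice_transcript", "author_id": "parent-03"}
{"note_id": "sample-med-2", "text": "Yesterday we started…gabapentin at a rate of 2.6 ml that will continue for one week, then we will switch rate to 2 ml over the course of another week, then 1.6 ml for another week with final rate at 0.6 ml...", "authored_at": "2020-11-08T20:05:00", "modality": "voice_transcript", "author_id": "parent-04"}
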